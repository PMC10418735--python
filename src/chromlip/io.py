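"""CSV readers and writers for the pipeline's documented schemas.

Schemas (one header row, "." decimal separator, UTF-8):

* ``hplc_runs.csv`` — compound_id, phi, t_r_min, t_m_min, replicate
* ``tlc_runs.csv`` — compound_id, phi, r_f, replicate
* ``calc_logp.csv`` — compound_id, milogP, AlogPs, AClogP, ALOGP, MLOGP,
  XLOGP2, XLOGP3
* ``adme.csv`` — compound_id, log_s, caco2_log_papp, hia_pct, vdss_log,
  bbb_log_bb, fu, cyp2d6, cyp3a4, cyp1a2, cyp2c19, cyp2c9, cl_tot

Validation failures raise :class:`~chromlip.core.ParseError` naming the row
(1-based, counting the header as row 1) and column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .core import CALCULATORS, CYP_ISOFORMS, ADMEProfile, CalcLogPSet, ParseError
from .hplc import HplcRun
from .model import LipophilicityFit
from .tlc import TlcRun

__all__ = [
    "read_hplc_csv",
    "read_tlc_csv",
    "read_calc_logp_csv",
    "read_adme_csv",
    "write_hplc_csv",
    "write_tlc_csv",
    "fits_to_frame",
    "write_fits_csv",
]

PathLike = Union[str, Path]


def _load(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    return df


def _num(df_name: str, row_idx: int, col: str, raw) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"{df_name} row {row_idx + 2}, column {col!r}: "
            f"non-numeric value {raw!r}"
        ) from None
    if math.isnan(v):
        raise ParseError(f"{df_name} row {row_idx + 2}, column {col!r}: missing value")
    return v


def _replicate(raw):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    return int(raw)


def read_hplc_csv(path: PathLike) -> list[HplcRun]:
    """Read isocratic HPLC runs; Φ and time preconditions surface as ParseError."""
    df = _load(path, ["compound_id", "phi", "t_r_min", "t_m_min"])
    name = Path(path).name
    runs = []
    for i, row in df.iterrows():
        try:
            runs.append(HplcRun(
                compound_id=row["compound_id"],
                phi=_num(name, i, "phi", row["phi"]),
                t_r=_num(name, i, "t_r_min", row["t_r_min"]),
                t_m=_num(name, i, "t_m_min", row["t_m_min"]),
                replicate=_replicate(row.get("replicate")),
            ))
        except ParseError:
            raise
        except ValueError as e:
            raise ParseError(f"{name} row {i + 2}: {e}") from None
    return runs


def read_tlc_csv(path: PathLike) -> list[TlcRun]:
    """Read TLC plate readings; out-of-range R_F is an error, never clipped."""
    df = _load(path, ["compound_id", "phi", "r_f"])
    name = Path(path).name
    runs = []
    for i, row in df.iterrows():
        try:
            runs.append(TlcRun(
                compound_id=row["compound_id"],
                phi=_num(name, i, "phi", row["phi"]),
                r_f=_num(name, i, "r_f", row["r_f"]),
                replicate=_replicate(row.get("replicate")),
            ))
        except ParseError:
            raise
        except ValueError as e:
            raise ParseError(f"{name} row {i + 2}: {e}") from None
    return runs


def read_calc_logp_csv(path: PathLike) -> dict[str, CalcLogPSet]:
    """Read the seven-calculator logP table keyed by compound id."""
    df = _load(path, ["compound_id", *CALCULATORS])
    name = Path(path).name
    out: dict[str, CalcLogPSet] = {}
    for i, row in df.iterrows():
        cid = row["compound_id"]
        if cid in out:
            raise ParseError(f"{name} row {i + 2}: duplicated compound_id {cid!r}")
        out[cid] = CalcLogPSet(
            compound_id=cid,
            values={c: _num(name, i, c, row[c]) for c in CALCULATORS},
        )
    return out


def read_adme_csv(path: PathLike) -> dict[str, ADMEProfile]:
    """Read combined ADME descriptor + CYP flag table keyed by compound id."""
    cyp_cols = [iso.lower() for iso in CYP_ISOFORMS]
    numeric = ["log_s", "caco2_log_papp", "hia_pct", "vdss_log", "bbb_log_bb", "fu",
               "cl_tot"]
    df = _load(path, ["compound_id", *numeric, *cyp_cols])
    name = Path(path).name
    out: dict[str, ADMEProfile] = {}
    for i, row in df.iterrows():
        cid = row["compound_id"]
        if cid in out:
            raise ParseError(f"{name} row {i + 2}: duplicated compound_id {cid!r}")
        flags = {}
        for iso in CYP_ISOFORMS:
            raw = str(row[iso.lower()]).strip().lower()
            if raw not in ("yes", "no", "true", "false"):
                raise ParseError(
                    f"{name} row {i + 2}, column {iso.lower()!r}: "
                    f"expected yes/no, got {row[iso.lower()]!r}"
                )
            flags[iso] = raw in ("yes", "true")
        try:
            out[cid] = ADMEProfile(
                compound_id=cid,
                **{c: _num(name, i, c, row[c]) for c in numeric[:-1]},
                cyp_inhibition=flags,
                cl_tot=_num(name, i, "cl_tot", row["cl_tot"]),
            )
        except ValueError as e:
            if isinstance(e, ParseError):
                raise
            raise ParseError(f"{name} row {i + 2}: {e}") from None
    return out


def _dec(x: float) -> str:
    # shortest decimal string that round-trips the float exactly
    return repr(float(x))


def write_hplc_csv(runs: Sequence[HplcRun], path: PathLike) -> None:
    pd.DataFrame(
        [{"compound_id": r.compound_id, "phi": _dec(r.phi),
          "t_r_min": _dec(r.t_r), "t_m_min": _dec(r.t_m),
          "replicate": r.replicate} for r in runs]
    ).to_csv(path, index=False)


def write_tlc_csv(runs: Sequence[TlcRun], path: PathLike) -> None:
    pd.DataFrame(
        [{"compound_id": r.compound_id, "phi": _dec(r.phi), "r_f": _dec(r.r_f),
          "replicate": r.replicate} for r in runs]
    ).to_csv(path, index=False)


def fits_to_frame(fits: Sequence[LipophilicityFit]) -> pd.DataFrame:
    """Tabulate fit results, one row per compound × technique."""
    return pd.DataFrame(
        [{
            "compound_id": f.compound_id,
            "technique": f.technique,
            "intercept": f.intercept,
            "slope": f.slope,
            "phi0": f.phi0,
            "abs_correlation": f.abs_correlation,
            "n_points": f.n_points,
            "residual_sd": f.residual_sd,
        } for f in fits]
    )


def write_fits_csv(fits: Sequence[LipophilicityFit], path: PathLike) -> None:
    fits_to_frame(fits).to_csv(path, index=False)
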
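"""Bundled reference dataset: 28 2-aminothiazol-4(5H)-one derivatives.

The package ships, as plain CSV, the published study-level tables for a
series of 28 pseudothiohydantoin (2-aminothiazol-4(5H)-one) derivatives
with 11β-HSD1 inhibitory activity: per-compound retention-line parameters
from both RP-HPLC (log kw, S, Φ0, |r|) and RP-TLC (R_M0, S, Φ0, |r|), seven
calculated logP values per compound, and pkCSM-predicted ADME descriptors.

Provenance notes on the transcription:

* the source tables print the slope column as −S (a positive number); the
  fixture stores the signed slope, so log k = intercept + slope·Φ holds
  literally with slope < 0;
* one milogP entry (compound 22) is printed with a stray space ("3. 75")
  and is stored as 3.75;
* compound 1's water solubility appears once in running text with a
  positive sign; the tabulated value (−1.477 log mol/L) is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import (
    CYP_ISOFORMS,
    ADMEProfile,
    CalcLogPSet,
    CompoundRecord,
    ParseError,
    check_unique_ids,
)
from .model import extrapolate_phi0

__all__ = ["TabulatedFit", "FixtureDataset", "load_fixture_dataset"]

N_COMPOUNDS = 28


@dataclass(frozen=True)
class TabulatedFit:
    """One published retention-line fit, as printed (Φ0 to 3 decimals)."""

    compound_id: str
    technique: str
    intercept: float
    slope: float
    phi0: float
    abs_correlation: float

    @property
    def phi0_recomputed(self) -> float:
        """Φ0 recomputed from the printed intercept and slope."""
        return extrapolate_phi0(self.intercept, self.slope)


@dataclass(frozen=True)
class FixtureDataset:
    """The full bundled dataset keyed by compound id ("1".."28")."""

    compounds: dict[str, CompoundRecord]
    fits: dict[tuple[str, str], TabulatedFit]
    calc_logp: dict[str, CalcLogPSet]
    adme: dict[str, ADMEProfile]

    @property
    def compound_ids(self) -> list[str]:
        return list(self.compounds)

    def intercept_column(self, technique: str) -> dict[str, float]:
        """Mapping compound → intercept (log kw or R_M0) for one technique."""
        return {
            cid: self.fits[(cid, technique)].intercept for cid in self.compounds
        }

    @property
    def log_kw(self) -> dict[str, float]:
        return self.intercept_column("RP-HPLC")

    @property
    def rm0(self) -> dict[str, float]:
        return self.intercept_column("RP-TLC")


def _read(name: str) -> pd.DataFrame:
    with resources.files("chromlip.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype={"compound_id": str})


def load_fixture_dataset() -> FixtureDataset:
    """Load and validate the bundled tables.

    Returns a :class:`FixtureDataset` with 28 compounds, 28 × 2 retention
    fits, 28 × 7 calculated logP values and 28 ADME profiles. A missing or
    duplicated compound id in any file raises :class:`ParseError` naming
    the offending row.
    """
    comp_df = _read("compounds.csv")
    check_unique_ids(list(comp_df["compound_id"]), "compounds.csv")
    compounds = {}
    for _, row in comp_df.iterrows():
        spiro = row["spiro"] if isinstance(row["spiro"], str) and row["spiro"] else None
        compounds[row["compound_id"]] = CompoundRecord(
            compound_id=row["compound_id"],
            series=row["series"],
            r1=row["r1"] if isinstance(row["r1"], str) else "",
            r2=row["r2"] if isinstance(row["r2"], str) else "",
            spiro=spiro,
        )

    fits_df = _read("fits_table1.csv")
    fits: dict[tuple[str, str], TabulatedFit] = {}
    for i, row in fits_df.iterrows():
        key = (row["compound_id"], row["technique"])
        if key in fits:
            raise ParseError(
                f"fits_table1.csv row {i + 2}: duplicated fit for compound "
                f"{key[0]!r}, technique {key[1]!r}"
            )
        if key[0] not in compounds:
            raise ParseError(
                f"fits_table1.csv row {i + 2}: unknown compound_id {key[0]!r}"
            )
        fits[key] = TabulatedFit(
            compound_id=row["compound_id"],
            technique=row["technique"],
            intercept=float(row["intercept"]),
            slope=float(row["slope"]),
            phi0=float(row["phi0"]),
            abs_correlation=float(row["abs_correlation"]),
        )
    for cid in compounds:
        for tech in ("RP-HPLC", "RP-TLC"):
            if (cid, tech) not in fits:
                raise ParseError(
                    f"fits_table1.csv: missing {tech} fit for compound {cid!r}"
                )

    calc_df = _read("calc_logp_table2.csv")
    check_unique_ids(list(calc_df["compound_id"]), "calc_logp_table2.csv")
    calc_logp = {
        row["compound_id"]: CalcLogPSet(
            compound_id=row["compound_id"],
            values={c: float(row[c]) for c in calc_df.columns if c != "compound_id"},
        )
        for _, row in calc_df.iterrows()
    }

    adme_df = _read("adme_table3.csv")
    cyp_df = _read("cyp_table4.csv").set_index("compound_id")
    check_unique_ids(list(adme_df["compound_id"]), "adme_table3.csv")
    check_unique_ids(list(cyp_df.index), "cyp_table4.csv")
    adme = {}
    for _, row in adme_df.iterrows():
        cid = row["compound_id"]
        if cid not in cyp_df.index:
            raise ParseError(f"cyp_table4.csv: missing compound_id {cid!r}")
        cyp_row = cyp_df.loc[cid]
        adme[cid] = ADMEProfile(
            compound_id=cid,
            log_s=float(row["log_s"]),
            caco2_log_papp=float(row["caco2_log_papp"]),
            hia_pct=float(row["hia_pct"]),
            vdss_log=float(row["vdss_log"]),
            bbb_log_bb=float(row["bbb_log_bb"]),
            fu=float(row["fu"]),
            cyp_inhibition={
                iso: str(cyp_row[iso.lower()]).strip().lower() == "yes"
                for iso in CYP_ISOFORMS
            },
            cl_tot=float(cyp_row["cl_tot"]),
        )

    for name, mapping in (("calc_logp_table2.csv", calc_logp),
                          ("adme tables", adme)):
        missing = sorted(set(compounds) - set(mapping), key=int)
        if missing:
            raise ParseError(f"{name}: missing compound id(s) {missing}")

    return FixtureDataset(compounds=compounds, fits=fits,
                          calc_logp=calc_logp, adme=adme)
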
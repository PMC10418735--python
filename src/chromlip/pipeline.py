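"""End-to-end pipeline: raw runs → fits → concordance → druglikeness screen.

:func:`run_pipeline` accepts raw per-compound measurement CSVs for either
or both techniques (or the bundled study tables), fits the retention lines,
compares the experimental indices with calculated logP, applies the
Lipinski lipophilicity criterion and the ADME classifications, and returns
a :class:`ReportBundle` of tidy tables plus a human-readable text report.
Compounds whose fits fail are reported in the bundle, not fatal.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .adme import adme_summary, classify_bbb, classify_caco2, classify_hia, \
    classify_vdss, count_cyp_inhibitors
from .comparison import closest_calculators, concordance_counts, \
    lipinski_lipophilicity_flag, paired_difference_report, summarize_range
from .core import CALCULATORS, CYP_ISOFORMS, ChromlipError, InvalidInputError
from .datasets import load_fixture_dataset
from .hplc import build_log_k_series, fit_retention_line
from .io import read_adme_csv, read_calc_logp_csv, read_hplc_csv, read_tlc_csv
from .model import extrapolate_phi0
from .tlc import build_rm_series, fit_rm_line

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either raw measurement CSVs (``hplc_csv``/``tlc_csv``) or
    ``use_fixture_tables=True`` must supply at least one technique.
    """

    hplc_csv: Optional[PathLike] = None
    tlc_csv: Optional[PathLike] = None
    calc_logp_csv: Optional[PathLike] = None
    adme_csv: Optional[PathLike] = None
    use_fixture_tables: bool = False
    out_dir: Optional[PathLike] = None

    def digest(self) -> str:
        """Short stable hash of the configuration, for run provenance."""
        blob = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Tidy result tables from one pipeline run."""

    fits: pd.DataFrame
    concordance: Optional[pd.DataFrame] = None
    lipinski: Optional[pd.DataFrame] = None
    adme_classes: Optional[pd.DataFrame] = None
    failures: dict[str, str] = field(default_factory=dict)
    report_text: str = ""

    def write(self, out_dir: PathLike) -> None:
        """Write every table as CSV plus the text report into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(out / "fits.csv", index=False)
        for name in ("concordance", "lipinski", "adme_classes"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.txt").write_text(self.report_text)


def _fit_runs(runs, build, fit, failures):
    by_compound = defaultdict(list)
    for r in runs:
        by_compound[r.compound_id].append(r)
    fits = []
    for cid in sorted(by_compound, key=str):
        try:
            fits.append(fit(build(by_compound[cid])))
        except InvalidInputError as e:
            failures[cid] = str(e)
    return fits


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the pipeline described by ``config``; see module docstring."""
    failures: dict[str, str] = {}
    rows = []
    fixture = load_fixture_dataset() if config.use_fixture_tables else None

    if config.hplc_csv is not None:
        for f in _fit_runs(read_hplc_csv(config.hplc_csv),
                           build_log_k_series, fit_retention_line, failures):
            rows.append(_fit_row(f.compound_id, f.technique, f.intercept,
                                 f.slope, f.phi0, f.abs_correlation))
    if config.tlc_csv is not None:
        for f in _fit_runs(read_tlc_csv(config.tlc_csv),
                           build_rm_series, fit_rm_line, failures):
            rows.append(_fit_row(f.compound_id, f.technique, f.intercept,
                                 f.slope, f.phi0, f.abs_correlation))
    if config.use_fixture_tables:
        assert fixture is not None
        for (cid, tech), tf in fixture.fits.items():
            rows.append(_fit_row(
                cid, tech, tf.intercept, tf.slope,
                extrapolate_phi0(tf.intercept, tf.slope), tf.abs_correlation,
            ))

    if not rows:
        raise ChromlipError("no input series")
    fits_df = pd.DataFrame(rows)

    # Experimental logP column for screening: HPLC intercepts when present.
    hplc_df = fits_df[fits_df["technique"] == "RP-HPLC"]
    tlc_df = fits_df[fits_df["technique"] == "RP-TLC"]
    logkw = dict(zip(hplc_df["compound_id"], hplc_df["intercept"]))
    rm0 = dict(zip(tlc_df["compound_id"], tlc_df["intercept"]))
    experimental = logkw or rm0

    if config.calc_logp_csv is not None:
        calc_sets = read_calc_logp_csv(config.calc_logp_csv)
    elif config.use_fixture_tables and fixture is not None:
        calc_sets = fixture.calc_logp
    else:
        calc_sets = None

    concordance_df = None
    if calc_sets:
        shared = sorted(set(experimental) & set(calc_sets), key=str)
        conc_rows = []
        for cid in shared:
            tie = closest_calculators(experimental[cid], calc_sets[cid])
            conc_rows.append({
                "compound_id": cid,
                "experimental": experimental[cid],
                "closest": "|".join(sorted(tie)),
                **{c: calc_sets[cid].values[c] for c in CALCULATORS},
            })
        concordance_df = pd.DataFrame(conc_rows)

    lipinski_df = pd.DataFrame(
        [{"compound_id": cid, "experimental_logp": v,
          "lipinski_pass": lipinski_lipophilicity_flag(v)}
         for cid, v in sorted(experimental.items(), key=lambda kv: str(kv[0]))]
    )

    if config.adme_csv is not None:
        adme = read_adme_csv(config.adme_csv)
    elif config.use_fixture_tables and fixture is not None:
        adme = fixture.adme
    else:
        adme = None

    adme_df = None
    if adme:
        adme_df = pd.DataFrame(
            [{
                "compound_id": p.compound_id,
                "caco2_class": classify_caco2(p.caco2_log_papp),
                "vdss_class": classify_vdss(p.vdss_log),
                "hia_class": classify_hia(p.hia_pct),
                "bbb_class": classify_bbb(p.bbb_log_bb),
                **{iso: p.cyp_inhibition.get(iso, False) for iso in CYP_ISOFORMS},
            } for p in adme.values()]
        )

    report = _render_report(config, fits_df, logkw, rm0, calc_sets,
                            experimental, lipinski_df, adme, failures)
    bundle = ReportBundle(fits=fits_df, concordance=concordance_df,
                          lipinski=lipinski_df, adme_classes=adme_df,
                          failures=failures, report_text=report)
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


def _fit_row(cid, tech, intercept, slope, phi0, abs_r):
    return {"compound_id": cid, "technique": tech,
            "intercept": round(float(intercept), 2),
            "slope": round(float(slope), 2),
            "phi0": round(float(phi0), 3),
            "abs_correlation": round(float(abs_r), 3)}


def _render_report(config, fits_df, logkw, rm0, calc_sets, experimental,
                   lipinski_df, adme, failures) -> str:
    lines = [
        "chromlip pipeline report",
        f"  package version : {__version__}",
        f"  config hash     : {config.digest()}",
        f"  fits            : {len(fits_df)} "
        f"({(fits_df['technique'] == 'RP-HPLC').sum()} RP-HPLC, "
        f"{(fits_df['technique'] == 'RP-TLC').sum()} RP-TLC)",
    ]
    if logkw:
        lo, hi = summarize_range(logkw.values())
        lines.append(f"  log kw range    : {lo:.2f} – {hi:.2f}")
    if rm0:
        lo, hi = summarize_range(rm0.values())
        lines.append(f"  R_M0 range      : {lo:.2f} – {hi:.2f}")
    if logkw and set(logkw) == set(rm0) and logkw:
        _, n_pos = paired_difference_report(logkw, rm0)
        lines.append(f"  log kw > R_M0   : {n_pos}/{len(logkw)} compounds")
    n_pass = int(lipinski_df["lipinski_pass"].sum())
    lines.append(f"  Lipinski logP≤5 : {n_pass}/{len(lipinski_df)} pass")
    if calc_sets:
        shared = {cid: calc_sets[cid] for cid in experimental if cid in calc_sets}
        if shared:
            counts = concordance_counts(
                {cid: experimental[cid] for cid in shared}, shared)
            ranked = sorted(counts.items(), key=lambda kv: -kv[1])
            lines.append("  closest-calculator counts (ties credited): "
                         + ", ".join(f"{k}={v}" for k, v in ranked))
    if adme:
        profiles = list(adme.values())
        summary = adme_summary(profiles)
        sol = summary["log_s"]
        lines.append(f"  water solubility: logS {sol['min']:.3f} "
                     f"(cpd {sol['min_compound']}) – {sol['max']:.3f}")
        for iso in CYP_ISOFORMS:
            n, hits = count_cyp_inhibitors(profiles, iso)
            lines.append(f"  {iso} inhibitors : {n}"
                         + (f" ({', '.join(hits)})" if hits else ""))
    if failures:
        lines.append(f"  failed compounds: {len(failures)}")
        for cid, msg in failures.items():
            lines.append(f"    {cid}: {msg}")
    return "\n".join(lines) + "\n"
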
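"""End-to-end plate analysis: curves -> k' -> calibration -> ASE statistics.

``run_pipeline`` reproduces the full assay analysis on one plate: fit both
dye channels of every well with the two-step 4-parameter logistic, compute
the transformed fluorescence ratio k', build the standard curve from the
STANDARD wells (pure mixtures excluded by default), invert the UNKNOWN
wells' replicate-averaged k' to allele-fraction estimates, and summarise
per tissue (one-sample t-test against balanced 1:1 expression, one-way
ANOVA with Tukey HSD across tissues).  Every well contributes a log record
(branch, convergence, truncation, failures) sufficient to reconstruct the
results.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import (AlleleFrequencyEstimate, StandardCurve, StandardPoint,
                          build_standard_curve, estimate_frequency)
from .inference import AnovaResult, TissueSummary, anova_across_tissues, tissue_summary
from .io import SampleSheetEntry, read_fluorescence_csv, read_sample_sheet
from .kprime import KPrimeResult, k_prime_for_reaction
from .sigmoid import FluorescenceCurve, NoAmplificationError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_plate"]


@dataclass
class PipelineConfig:
    exclude_pure: bool = True
    assay: str = "cDNA"
    alpha: float = 0.05
    posthoc: str = "tukey"
    tol: float = 1e-10
    max_iter: int = 2000


@dataclass
class PipelineResult:
    kprime_table: pd.DataFrame
    standard_points: list[StandardPoint]
    standard_curve: StandardCurve | None
    estimates: list[AlleleFrequencyEstimate]
    tissue_summaries: list[TissueSummary]
    anova: AnovaResult | None
    log: list[dict] = field(default_factory=list)

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"sample_id": e.sample_id, "tissue": e.tissue,
             "n_replicates": len(e.k_values), "k_mean": e.k_mean,
             "x_hat": e.x_hat, "clamped": e.clamped}
            for e in self.estimates
        ])

    def stats_report(self) -> dict:
        report: dict = {"tissues": [], "anova": None, "calibration": None}
        if self.standard_curve is not None:
            c = self.standard_curve
            report["calibration"] = {
                "assay": c.assay, "slope": c.slope, "intercept": c.intercept,
                "r_squared": c.r_squared, "n_points": c.n_points,
                "excluded_pure": c.excluded_pure,
            }
        for s in self.tissue_summaries:
            report["tissues"].append({
                "tissue": s.tissue, "n_samples": s.n_samples,
                "mean_x": s.mean_x, "sd_x": s.sd_x,
                "t_vs_half": s.t_vs_half, "p_vs_half": s.p_vs_half,
                "significant_vs_half": s.significant_vs_half,
                "degenerate": s.degenerate,
            })
        if self.anova is not None:
            report["anova"] = {
                "f_stat": self.anova.f_stat,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "p_value": self.anova.p_value,
                "posthoc": [{"pair": list(pair), "p_adj": p}
                            for pair, p in self.anova.posthoc],
            }
        return report

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.kprime_table.to_csv(outdir / "kprime.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        if not self.estimates_frame().empty:
            self.estimates_frame().to_csv(outdir / "estimates.tsv", sep="\t",
                                          index=False, float_format="%.6g")
        with open(outdir / "stats.json", "w") as fh:
            json.dump(self.stats_report(), fh, indent=2)
        with open(outdir / "pipeline_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2)


def _fit_wells(curves: dict[tuple[str, str], FluorescenceCurve],
               wells: list[str], config: PipelineConfig,
               log: list[dict]) -> dict[str, KPrimeResult]:
    results: dict[str, KPrimeResult] = {}
    for well in wells:
        fam = curves.get((well, "FAM"))
        vic = curves.get((well, "VIC"))
        if fam is None or vic is None:
            log.append({"well": well, "status": "missing_channel"})
            continue
        try:
            res = k_prime_for_reaction(fam, vic, tol=config.tol,
                                       max_iter=config.max_iter)
        except NoAmplificationError as err:
            log.append({"well": well, "status": "no_amplification", "detail": str(err)})
            continue
        except ValueError as err:
            log.append({"well": well, "status": "fit_error", "detail": str(err)})
            continue
        results[well] = res
        log.append({
            "well": well, "status": "ok", "branch": res.branch.value,
            "k_prime": res.k_prime,
            "fam_truncation": res.fam_fit.truncation_cycle,
            "vic_truncation": res.vic_fit.truncation_cycle,
            "fam_converged": res.fam_fit.converged,
            "vic_converged": res.vic_fit.converged,
        })
    return results


def analyze_plate(curves: dict[tuple[str, str], FluorescenceCurve],
                  entries: list[SampleSheetEntry],
                  config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on in-memory curves and sample-sheet entries."""
    config = config or PipelineConfig()
    log: list[dict] = []
    sheet_wells = [e.well for e in entries]
    curve_wells = {w for w, _ in curves}
    missing = [w for w in sheet_wells if w not in curve_wells]
    if missing:
        raise ValueError(f"sample sheet references wells absent from fluorescence data: {missing}")

    standards = [e for e in entries if e.role == "STANDARD"]
    unknowns = [e for e in entries if e.role == "UNKNOWN"]
    if not standards:
        raise ValueError("cannot calibrate: no STANDARD wells in sample sheet")
    if len({e.x_true for e in standards}) < 3:
        raise ValueError("cannot calibrate: fewer than 3 distinct standard fractions")

    kprime = _fit_wells(curves, sheet_wells, config, log)

    rows = []
    for well, res in kprime.items():
        rows.append({
            "well": well, "branch": res.branch.value,
            "r_prime": res.r_prime, "k_prime": res.k_prime,
            "a_fam": res.fam_fit.a, "b_fam": res.fam_fit.b, "c_fam": res.fam_fit.c,
            "y0_fam": res.fam_fit.y0,
            "a_vic": res.vic_fit.a, "b_vic": res.vic_fit.b, "c_vic": res.vic_fit.c,
            "y0_vic": res.vic_fit.y0,
        })
    kprime_table = pd.DataFrame(rows)

    by_fraction: dict[float, list[float]] = defaultdict(list)
    for e in standards:
        if e.well in kprime:
            by_fraction[e.x_true].append(kprime[e.well].k_prime)
    points = [StandardPoint(x_true=x, k_values=tuple(ks))
              for x, ks in sorted(by_fraction.items()) if ks]
    usable = [p for p in points if not (config.exclude_pure and p.is_pure)]
    curve = None
    if len(usable) >= 3:
        curve = build_standard_curve(points, exclude_pure=config.exclude_pure,
                                     assay=config.assay)
    else:
        log.append({"status": "calibration_failed",
                    "detail": f"only {len(usable)} usable standard fractions"})

    estimates: list[AlleleFrequencyEstimate] = []
    if curve is not None:
        by_sample: dict[tuple[str, str], list[float]] = defaultdict(list)
        for e in unknowns:
            if e.well in kprime:
                by_sample[(e.sample_id, e.tissue)].append(kprime[e.well].k_prime)
        for (sample_id, tissue), ks in sorted(by_sample.items()):
            est = estimate_frequency(ks, curve, sample_id=sample_id, tissue=tissue)
            estimates.append(est)
            if est.clamped:
                log.append({"status": "clamped", "sample_id": sample_id,
                            "tissue": tissue, "x_hat": est.x_hat})

    summaries: list[TissueSummary] = []
    groups: dict[str, list[float]] = defaultdict(list)
    for est in estimates:
        groups[est.tissue].append(est.x_hat)
    for tissue in sorted(groups):
        if len(groups[tissue]) >= 2:
            summaries.append(tissue_summary(estimates, tissue, alpha=config.alpha))
    anova = None
    testable = {t: v for t, v in groups.items() if len(v) >= 2}
    if len(testable) >= 2:
        anova = anova_across_tissues(testable, posthoc=config.posthoc,
                                     alpha=config.alpha)
    return PipelineResult(kprime_table=kprime_table, standard_points=points,
                          standard_curve=curve, estimates=estimates,
                          tissue_summaries=summaries, anova=anova, log=log)


def run_pipeline(fluorescence_csv: str | Path, sample_sheet: str | Path,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """File-based entry point; optionally writes the results bundle to outdir."""
    curves = read_fluorescence_csv(fluorescence_csv)
    entries = read_sample_sheet(sample_sheet)
    result = analyze_plate(curves, entries, config=config)
    if outdir is not None:
        result.write(outdir)
    return result
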
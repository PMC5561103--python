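"""End-to-end analysis runs from a structured YAML config.

Each configured analysis names an exposure table, an outcome table and
optional LD matrix / exclusion-list / proxy-map files, and is evaluated on
two instrument sets — with the pleiotropy exclusions applied and with all
variants retained — so sensitivity to instrument validity is always visible.
Every run writes a machine-readable results table, a per-variant forest-plot
data table, and a provenance log naming every excluded variant and why.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, instruments, io, reporting


@dataclass
class AnalysisSpec:
    name: str
    exposure: Path
    outcome: Path
    ld_matrix: Path | None = None
    ld_index: Path | None = None
    exclusion_list: Path | None = None
    proxy_map: Path | None = None
    methods: list[str] = field(default_factory=lambda: ["ivw", "weighted_median", "egger"])
    exposure_columns: dict[str, str] | None = None
    outcome_columns: dict[str, str] | None = None
    palindrome_policy: str = "drop"
    eaf_window: float = 0.08
    p_threshold: float = instruments.GENOME_WIDE_P
    r2_threshold: float = instruments.LD_R2_THRESHOLD
    binary_outcome: bool = True
    n_boot: int = 1000


@dataclass
class RunConfig:
    analyses: list[AnalysisSpec]
    output_dir: Path
    alpha: float = 0.05
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        specs = []
        for a in raw["analyses"]:
            kwargs = dict(a)
            for key in ("exposure", "outcome", "ld_matrix", "ld_index",
                        "exclusion_list", "proxy_map"):
                if kwargs.get(key) is not None:
                    kwargs[key] = base / kwargs[key]
            specs.append(AnalysisSpec(**kwargs))
        seed = raw.get("seed")
        if seed is None and any("weighted_median" in s.methods for s in specs):
            raise ValueError("a seed is mandatory when weighted_median is requested")
        return cls(
            analyses=specs,
            output_dir=Path(raw.get("output_dir", "ssmr_out")),
            alpha=float(raw.get("alpha", 0.05)),
            seed=seed,
        )


@dataclass
class AnalysisResult:
    name: str
    ok: bool
    rows: list[dict] = field(default_factory=list)
    forest: list[dict] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunBundle:
    results: pd.DataFrame
    analyses: list[AnalysisResult]
    log: list[str]

    @property
    def ok(self) -> bool:
        return all(a.ok for a in self.analyses)


_RESULT_COLUMNS = [
    "analysis", "snp_set", "n_snps", "mean_F", "method", "estimate", "se",
    "ci_low", "ci_high", "ci_kind", "pvalue", "or", "or_ci_low", "or_ci_high",
    "Q", "Q_df", "Q_pvalue", "egger_intercept", "egger_intercept_pvalue",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.10g}"
    return str(x)


def _estimate_rows(
    h: io.HarmonizedTable,
    inst: instruments.InstrumentSet,
    spec: AnalysisSpec,
    snp_set: str,
    alpha: float,
    seed: int | None,
    rho: pd.DataFrame | None,
    log: list[str],
) -> tuple[list[dict], list[dict]]:
    sub = h.subset(inst.retained)
    m = len(sub)
    base = {"analysis": spec.name, "snp_set": snp_set, "n_snps": m, "mean_F": inst.mean_f}
    rows: list[dict] = []
    het: estimators.HeterogeneityResult | None = None
    intercept: estimators.MREstimate | None = None
    if m == 0:
        log.append(f"{spec.name}/{snp_set}: no instruments retained, nothing estimated")
        return rows, []
    if m >= 2:
        het = estimators.cochran_q(sub)
    ests: list[estimators.MREstimate] = []
    if "egger" in spec.methods and m >= 3:
        slope, intercept = estimators.mr_egger(sub, alpha=alpha)
    for method in spec.methods:
        try:
            if method == "ivw":
                if rho is not None:
                    sub_rho = rho.loc[sub.snps, sub.snps].to_numpy()
                    ests.append(estimators.ivw_correlated(sub, sub_rho, alpha=alpha))
                else:
                    ests.append(estimators.ivw_fixed(sub, alpha=alpha))
            elif method == "weighted_median":
                if m < 3:
                    log.append(f"{spec.name}/{snp_set}: weighted_median skipped ({m} SNPs < 3)")
                    continue
                ests.append(estimators.weighted_median(sub, n_boot=spec.n_boot, seed=seed, alpha=alpha))
            elif method == "egger":
                if m < 3:
                    log.append(f"{spec.name}/{snp_set}: MR-Egger skipped ({m} SNPs < 3)")
                    continue
                assert intercept is not None
                ests.append(slope)
            elif method == "wald":
                if m != 1:
                    log.append(f"{spec.name}/{snp_set}: wald applies to single-SNP sets only")
                    continue
                ests.append(
                    estimators.wald_ratio(
                        sub.beta_x[0], sub.se_x[0], sub.beta_y[0], sub.se_y[0], alpha=alpha
                    )
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError) as exc:
            log.append(f"{spec.name}/{snp_set}: {method} failed: {exc}")
    for est in ests:
        row = dict(base, method=est.method, estimate=est.estimate, se=est.se,
                   ci_low=est.ci_low, ci_high=est.ci_high, ci_kind=est.ci_kind,
                   pvalue=est.pvalue)
        if spec.binary_outcome:
            orr = reporting.to_odds_ratio(est)
            row.update({"or": orr.odds_ratio, "or_ci_low": orr.ci_low,
                        "or_ci_high": orr.ci_high})
        else:
            row.update({"or": math.nan, "or_ci_low": math.nan, "or_ci_high": math.nan})
        row.update({
            "Q": het.Q if het else math.nan,
            "Q_df": het.df if het else 0,
            "Q_pvalue": het.pvalue if het else math.nan,
            "egger_intercept": intercept.estimate if intercept else math.nan,
            "egger_intercept_pvalue": intercept.pvalue if intercept else math.nan,
        })
        rows.append(row)
    forest = []
    for j, snp in enumerate(sub.snps):
        try:
            w = estimators.wald_ratio(sub.beta_x[j], sub.se_x[j], sub.beta_y[j], sub.se_y[j], alpha)
        except ZeroDivisionError:
            continue
        forest.append({"analysis": spec.name, "snp_set": snp_set, "SNP": snp,
                       "estimate": w.estimate, "se": w.se, "ci_low": w.ci_low,
                       "ci_high": w.ci_high})
    return rows, forest


def run_analysis(spec: AnalysisSpec, alpha: float, seed: int | None) -> AnalysisResult:
    res = AnalysisResult(spec.name, ok=False)
    log = res.log
    try:
        exposure, rej_x = io.read_association_table(spec.exposure, spec.exposure_columns)
        outcome, rej_y = io.read_association_table(spec.outcome, spec.outcome_columns)
        for label, rej in (("exposure", rej_x), ("outcome", rej_y)):
            for r in rej:
                log.append(f"{spec.name}: {label} row {r.line} rejected: {r.reason}")
        if spec.proxy_map is not None:
            proxies = io.read_proxy_map(spec.proxy_map)
            outcome, proxy_report = io.apply_proxy_map(outcome, proxies)
            for target, proxy in proxy_report.substituted.items():
                log.append(f"{spec.name}: {proxy} used as a proxy for {target}")
            for target in proxy_report.unavailable:
                log.append(f"{spec.name}: {target} unavailable and no proxy found")
        ld = (
            io.read_ld_matrix(spec.ld_matrix, spec.ld_index)
            if spec.ld_matrix is not None
            else None
        )
        exclusions = (
            io.read_exclusion_list(spec.exclusion_list)
            if spec.exclusion_list is not None
            else None
        )
        no_pleio, all_snps, sel_log = instruments.select_instruments(
            exposure,
            ld=ld,
            pleiotropy_list=exclusions,
            available={r.variant_id for r in outcome},
            p_threshold=spec.p_threshold,
            r2_threshold=spec.r2_threshold,
        )
        log.extend(f"{spec.name}: {line}" for line in sel_log)
        for inst in (no_pleio, all_snps):
            for e in inst.excluded:
                log.append(f"{spec.name}: excluded {e.variant_id} ({e.reason}) {e.detail}")
            break  # all_snps shares the pre-pleiotropy exclusions already logged
        h = io.harmonize(exposure, outcome, spec.palindrome_policy, spec.eaf_window)
        for snp, action, why in h.decisions:
            if action == "dropped":
                log.append(f"{spec.name}: harmonization dropped {snp}: {why}")
        # harmonization drops count as unavailability for instrument accounting
        harmonized_ids = set(h.snps)
        for inst in (no_pleio, all_snps):
            lost = [v for v in inst.retained if v not in harmonized_ids]
            inst.retained = [v for v in inst.retained if v in harmonized_ids]
            inst.excluded += [
                instruments.Exclusion(v, "unavailable", "dropped in harmonization")
                for v in lost
            ]
        for snp_set, inst in (("without_pleiotropy", no_pleio), ("all_snps", all_snps)):
            rows, forest = _estimate_rows(h, inst, spec, snp_set, alpha, seed, ld, log)
            res.rows.extend(rows)
            res.forest.extend(forest)
        res.ok = True
    except Exception as exc:  # analysis-level isolation: one failure must not kill the run
        res.error = f"{type(exc).__name__}: {exc}"
        log.append(f"{spec.name}: FAILED: {res.error}")
    return res


def run(config: RunConfig) -> RunBundle:
    """Execute every configured analysis and write the result bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    analyses = [run_analysis(spec, config.alpha, config.seed) for spec in config.analyses]
    all_rows = [row for a in analyses for row in a.rows]
    results = pd.DataFrame(all_rows, columns=_RESULT_COLUMNS)
    log = [line for a in analyses for line in a.log]

    with (outdir / "results.tsv").open("w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for row in all_rows:
            fh.write("\t".join(_fmt(row[c]) for c in _RESULT_COLUMNS) + "\n")
    forest_cols = ["analysis", "snp_set", "SNP", "estimate", "se", "ci_low", "ci_high"]
    with (outdir / "forest_data.tsv").open("w") as fh:
        fh.write("\t".join(forest_cols) + "\n")
        for a in analyses:
            for row in a.forest:
                fh.write("\t".join(_fmt(row[c]) for c in forest_cols) + "\n")
    (outdir / "run.log").write_text("".join(line + "\n" for line in log))
    return RunBundle(results, analyses, log)
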
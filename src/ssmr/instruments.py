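"""Instrument selection: significance filtering, LD pruning, pleiotropy
exclusion, and instrument-strength (F-statistic) accounting.

The filters mirror standard two-sample MR practice: only variants reaching
genome-wide significance for the exposure are eligible; of any pair with
squared LD correlation above a threshold the one with the weaker exposure
association is discarded; variants with known associations with the outcome
through pathways other than the exposure are set aside (but retrievable, so
analyses with and without them can be reported side by side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantAssociation

GENOME_WIDE_P = 5e-8
LD_R2_THRESHOLD = 0.7


@dataclass
class Exclusion:
    variant_id: str
    reason: str  # 'ld' | 'pleiotropy' | 'unavailable' | 'subthreshold'
    detail: str = ""


@dataclass
class InstrumentSet:
    """Selected instruments plus the provenance of every exclusion."""

    retained: list[str] = field(default_factory=list)
    excluded: list[Exclusion] = field(default_factory=list)
    f_stats: dict[str, float] = field(default_factory=dict)

    @property
    def mean_f(self) -> float:
        if not self.retained:
            return float("nan")
        return float(np.mean([self.f_stats[v] for v in self.retained]))

    def validate(self) -> None:
        overlap = set(self.retained) & {e.variant_id for e in self.excluded}
        if overlap:
            raise ValueError(f"variants both retained and excluded: {sorted(overlap)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"SNP": v, "status": "retained", "reason": "", "detail": "", "F": self.f_stats.get(v)}
            for v in self.retained
        ] + [
            {"SNP": e.variant_id, "status": "excluded", "reason": e.reason, "detail": e.detail,
             "F": self.f_stats.get(e.variant_id)}
            for e in self.excluded
        ]
        return pd.DataFrame(rows, columns=["SNP", "status", "reason", "detail", "F"])


def variant_f_statistic(beta_x: float, se_x: float) -> float:
    """Per-variant instrument strength, the squared z-score (beta/se)^2."""
    if not se_x > 0:
        raise ValueError(f"se_x must be positive, got {se_x}")
    return (beta_x / se_x) ** 2


def f_statistic_from_r2(r2: float, n: float, k: int = 1) -> float:
    """Alternative F approximation from variance explained: R2(n-k-1)/(k(1-R2))."""
    if not (0 < r2 < 1) or n <= k + 1:
        raise ValueError("need 0 < r2 < 1 and n > k+1")
    return r2 * (n - k - 1) / (k * (1 - r2))


def filter_genome_wide(
    table: Sequence[VariantAssociation], threshold: float = GENOME_WIDE_P
) -> tuple[list[VariantAssociation], list[Exclusion]]:
    """Partition on strict genome-wide significance: retained iff p < threshold."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    retained = [r for r in table if r.pvalue < threshold]
    excluded = [
        Exclusion(r.variant_id, "subthreshold", f"p={r.pvalue:.3g} >= {threshold:.3g}")
        for r in table
        if r.pvalue >= threshold
    ]
    return retained, excluded


def ld_prune(
    table: Sequence[VariantAssociation],
    ld: pd.DataFrame,
    r2_threshold: float = LD_R2_THRESHOLD,
) -> tuple[list[VariantAssociation], list[Exclusion], list[str]]:
    """Discard the weaker member of every highly correlated pair.

    Pairs with r^2 > ``r2_threshold`` are visited in descending r^2 (ties
    broken lexicographically on the rsID pair); at each still-live pair the
    member with the larger exposure p-value (ties: lexicographically larger
    rsID) is excluded, recording its retained partner.  Exclusions cascade:
    an excluded variant cannot knock out further variants.  Variants absent
    from the LD index are treated as uncorrelated and listed in the returned
    log.
    """
    by_id = {r.variant_id: r for r in table}
    missing = [v for v in by_id if v not in ld.index]
    in_ld = [v for v in by_id if v in ld.index]
    pairs = []
    for i, a in enumerate(in_ld):
        for b in in_ld[i + 1:]:
            r2 = float(ld.loc[a, b]) ** 2
            if r2 > r2_threshold:
                pairs.append((r2, *sorted((a, b))))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: dict[str, str] = {}
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        pa, pb = by_id[a].pvalue, by_id[b].pvalue
        loser = (max(a, b) if pa == pb else (a if pa > pb else b))
        dropped[loser] = a if loser == b else b
    retained = [r for r in table if r.variant_id not in dropped]
    excluded = [
        Exclusion(v, "ld", f"r2 > {r2_threshold} with retained {partner}")
        for v, partner in dropped.items()
    ]
    return retained, excluded, [f"{v}: absent from LD index, treated as uncorrelated" for v in missing]


def exclude_pleiotropic(
    table: Sequence[VariantAssociation],
    exclusion_list: Mapping[str, str],
) -> tuple[list[VariantAssociation], list[Exclusion], list[str]]:
    """Set aside variants with known outcome associations off the exposure path.

    Returns (retained, excluded, log).  Listed variants absent from the table
    are logged and ignored.  Callers keep the full table, so the analysis
    including these variants stays available.
    """
    present = {r.variant_id for r in table}
    retained = [r for r in table if r.variant_id not in exclusion_list]
    excluded = [
        Exclusion(v, "pleiotropy", note) for v, note in exclusion_list.items() if v in present
    ]
    log = [f"{v}: listed for pleiotropy but not in table" for v in exclusion_list if v not in present]
    return retained, excluded, log


def select_instruments(
    table: Sequence[VariantAssociation],
    ld: pd.DataFrame | None = None,
    pleiotropy_list: Mapping[str, str] | None = None,
    available: set[str] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = LD_R2_THRESHOLD,
) -> tuple[InstrumentSet, InstrumentSet, list[str]]:
    """Full selection cascade; returns (without-pleiotropy set, all-SNPs set, log).

    Order: significance filter, LD pruning, availability in the outcome study
    (``available`` = outcome rsIDs; None skips the check), then pleiotropy.
    The second InstrumentSet retains the pleiotropic variants, mirroring
    reporting of both SNP sets.
    """
    log: list[str] = []
    retained, excl = filter_genome_wide(table, p_threshold)
    exclusions = list(excl)
    if ld is not None:
        retained, ld_excl, ld_log = ld_prune(retained, ld, r2_threshold)
        exclusions += ld_excl
        log += ld_log
    if available is not None:
        unavailable = [r for r in retained if r.variant_id not in available]
        retained = [r for r in retained if r.variant_id in available]
        exclusions += [
            Exclusion(r.variant_id, "unavailable", "absent from outcome study, no proxy")
            for r in unavailable
        ]
    f_stats = {r.variant_id: variant_f_statistic(r.beta, r.se) for r in retained}
    all_set = InstrumentSet([r.variant_id for r in retained], list(exclusions), dict(f_stats))
    if pleiotropy_list:
        kept, pl_excl, pl_log = exclude_pleiotropic(retained, pleiotropy_list)
        log += pl_log
        no_pl = InstrumentSet([r.variant_id for r in kept], exclusions + pl_excl, dict(f_stats))
    else:
        no_pl = InstrumentSet(list(all_set.retained), list(exclusions), dict(f_stats))
    no_pl.validate()
    all_set.validate()
    return no_pl, all_set, log
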
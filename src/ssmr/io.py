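"""Reading, validation and harmonization of GWAS summary statistics.

Summary-statistic tables are delimited text with one row per variant.  The
canonical header is ``SNP, effect_allele, other_allele, eaf, beta, se, pval,
n``; a ``column_map`` translates arbitrary consortium headers onto it.
Harmonization aligns the outcome table onto the exposure table's effect
alleles, flipping outcome betas (and complementing allele frequencies) where
the two studies reported opposite alleles or opposite strands, and handling
strand-ambiguous palindromic variants by policy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
MANDATORY_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class ConfigurationError(ValueError):
    """A table cannot be read at all (missing mandatory columns, bad map)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the effect per effect-allele copy, on the trait's analysis
    scale (per SD for continuous traits, log odds for binary ones).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: p-value must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must be in [0,1], got {self.eaf}")
        if self.n is not None and not (self.n > 0):
            raise ValueError(f"{self.variant_id}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class RowError:
    """A rejected input row: 1-based line number and the reason."""

    line: int
    reason: str


@dataclass
class ProxyMap:
    """Target rsID -> proxy rsID substitutions for unavailable variants."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_proxies: dict[str, str] = {}
        for target, proxy in self.pairs.items():
            if target == proxy:
                raise ValueError(f"proxy map: {target} maps to itself")
            if proxy in seen_proxies:
                raise ValueError(
                    f"proxy map: {proxy} is the proxy of both {seen_proxies[proxy]} and {target}"
                )
            seen_proxies[proxy] = target


@dataclass
class HarmonizedTable:
    """Per-variant exposure/outcome effect pairs on a common effect allele.

    ``table`` columns: SNP, beta_x, se_x, beta_y, se_y, eaf_x, orientation
    (one of 'unchanged', 'flipped'); ``decisions`` records every variant that
    entered harmonization and what happened to it.
    """

    table: pd.DataFrame
    decisions: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(float)

    @property
    def snps(self) -> list[str]:
        return self.table["SNP"].tolist()

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedTable":
        keep = set(variant_ids)
        sub = self.table[self.table["SNP"].isin(keep)].reset_index(drop=True)
        return HarmonizedTable(sub, list(self.decisions))

    @classmethod
    def from_arrays(
        cls,
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
        snps: Sequence[str] | None = None,
    ) -> "HarmonizedTable":
        m = len(beta_x)
        if snps is None:
            snps = [f"snp{i + 1}" for i in range(m)]
        df = pd.DataFrame(
            {
                "SNP": list(snps),
                "beta_x": np.asarray(beta_x, float),
                "se_x": np.asarray(se_x, float),
                "beta_y": np.asarray(beta_y, float),
                "se_y": np.asarray(se_y, float),
                "eaf_x": np.nan,
                "orientation": "unchanged",
            }
        )
        return cls(df)


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if text == "" or text.upper() in {"NA", "NAN", "NULL", "."}:
        return None
    return float(text)


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[VariantAssociation], list[RowError]]:
    """Read a summary-statistic table; returns (records, rejected rows).

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"SNP": "rsid", "beta": "b"}``.  Unmapped canonical names are looked up
    verbatim.  Rows failing validation (non-numeric or non-positive se, bad
    alleles, p outside (0,1]) are reported with their 1-based line number
    rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    sep = delimiter or _sniff_delimiter(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            raise ConfigurationError(f"{path}: empty file")
        header = [h.strip() for h in header]
        cmap = dict(column_map or {})
        index: dict[str, int] = {}
        for canonical in CANONICAL_COLUMNS:
            name = cmap.get(canonical, canonical)
            if name in header:
                index[canonical] = header.index(name)
        missing = [c for c in MANDATORY_COLUMNS if c not in index]
        if missing:
            raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")

        records: list[VariantAssociation] = []
        rejected: list[RowError] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                eaf = _parse_float(row[index["eaf"]]) if "eaf" in index else None
                n = _parse_float(row[index["n"]]) if "n" in index else None
                beta = _parse_float(row[index["beta"]])
                se = _parse_float(row[index["se"]])
                pval = _parse_float(row[index["pval"]])
                if beta is None or se is None or pval is None:
                    raise ValueError("non-numeric beta/se/pval")
                records.append(
                    VariantAssociation(
                        variant_id=row[index["SNP"]].strip(),
                        effect_allele=row[index["effect_allele"]].strip().upper(),
                        other_allele=row[index["other_allele"]].strip().upper(),
                        beta=beta,
                        se=se,
                        pvalue=pval,
                        eaf=eaf,
                        n=n,
                    )
                )
            except (ValueError, IndexError) as exc:
                rejected.append(RowError(line=lineno, reason=str(exc)))
    return records, rejected


def write_association_table(
    records: Iterable[VariantAssociation], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write records under the canonical header (missing eaf/n as NA)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.variant_id,
                    r.effect_allele,
                    r.other_allele,
                    "NA" if r.eaf is None else repr(r.eaf),
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pvalue),
                    "NA" if r.n is None else repr(r.n),
                ]
            )


def read_ld_matrix(matrix_path: str | Path, index_path: str | Path) -> pd.DataFrame:
    """Read a square signed-correlation matrix keyed by a one-column rsID file."""
    ids = [line.strip() for line in Path(index_path).read_text().splitlines() if line.strip()]
    mat = np.loadtxt(matrix_path, ndmin=2)
    if mat.shape != (len(ids), len(ids)):
        raise ConfigurationError(
            f"LD matrix shape {mat.shape} does not match {len(ids)} index variants"
        )
    if np.any(np.abs(mat) > 1 + 1e-12) or not np.allclose(np.diag(mat), 1.0):
        raise ConfigurationError("LD matrix entries must lie in [-1,1] with unit diagonal")
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_ld_matrix(ld: pd.DataFrame, matrix_path: str | Path, index_path: str | Path) -> None:
    np.savetxt(matrix_path, ld.to_numpy(), fmt="%.10g", delimiter="\t")
    Path(index_path).write_text("\n".join(map(str, ld.index)) + "\n")


def read_proxy_map(path: str | Path, delimiter: str | None = None) -> ProxyMap:
    """Read a two-column target/proxy file (header optional)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    pairs: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(sep)]
        if cells[0].lower() in {"target", "snp", "variant_id"}:
            continue
        if len(cells) < 2:
            raise ConfigurationError(f"{path}: proxy map rows need two columns, got {line!r}")
        pairs[cells[0]] = cells[1]
    return ProxyMap(pairs)


def read_exclusion_list(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read an exclusion list; returns variant_id -> annotation (may be '')."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(sep)]
        if cells[0].lower() in {"snp", "variant_id"}:
            continue
        out[cells[0]] = cells[1] if len(cells) > 1 else ""
    return out


@dataclass
class ProxyReport:
    substituted: dict[str, str] = field(default_factory=dict)  # target -> proxy used
    unavailable: list[str] = field(default_factory=list)  # neither target nor proxy found


def apply_proxy_map(
    table: Sequence[VariantAssociation],
    proxies: ProxyMap,
    proxy_source: Sequence[VariantAssociation] | None = None,
) -> tuple[list[VariantAssociation], ProxyReport]:
    """Substitute proxies for targets missing from ``table``.

    ``proxy_source`` is where proxy records are looked up (defaults to the
    table itself, covering the case where the proxy is present in the same
    file under its own rsID).  Targets already present are untouched; a target
    whose proxy is also absent is recorded unavailable, never raised.
    """
    present = {r.variant_id for r in table}
    source = {r.variant_id: r for r in (proxy_source if proxy_source is not None else table)}
    report = ProxyReport()
    out = list(table)
    for target, proxy in proxies.pairs.items():
        if target in present:
            continue
        if proxy in source:
            if proxy not in present:
                out.append(source[proxy])
            report.substituted[target] = proxy
        else:
            report.unavailable.append(target)
    return out, report


def _orient_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> str | None:
    """Return 'unchanged' / 'flipped' for a non-palindromic pair, None if
    the allele sets are incompatible even after strand complementing."""
    ea, oa = exp.effect_allele, exp.other_allele
    pairs = {
        (out.effect_allele, out.other_allele): "as-is",
        (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]): "complemented",
    }
    for (a1, a2) in pairs:
        if (a1, a2) == (ea, oa):
            return "unchanged"
        if (a1, a2) == (oa, ea):
            return "flipped"
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
) -> HarmonizedTable:
    """Align outcome effects onto the exposure effect alleles.

    Variants are matched by rsID.  When the outcome's effect allele is the
    exposure's other allele (directly or on the opposite strand) the outcome
    beta is sign-flipped and its eaf complemented.  Palindromic variants
    (A/T, C/G) carry no strand information; policy 'drop' removes them,
    'infer-by-eaf' orients them by allele frequency when both eafs are
    decisively away from 0.5 (outside 0.5 +/- eaf_window) and drops them
    otherwise.
    """
    if palindrome_policy not in {"drop", "infer-by-eaf"}:
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise ValueError("harmonize requires non-empty exposure and outcome tables")
    out_by_id = {r.variant_id: r for r in outcome}
    rows = []
    decisions: list[tuple[str, str, str]] = []
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            decisions.append((exp.variant_id, "dropped", "absent from outcome table"))
            continue
        if exp.is_palindromic or out.is_palindromic:
            if not (exp.is_palindromic and out.is_palindromic):
                decisions.append((exp.variant_id, "dropped", "allele mismatch"))
                continue
            if {exp.effect_allele, exp.other_allele} != {out.effect_allele, out.other_allele}:
                decisions.append((exp.variant_id, "dropped", "allele mismatch"))
                continue
            if palindrome_policy == "drop":
                decisions.append((exp.variant_id, "dropped", "palindromic"))
                continue
            if exp.eaf is None or out.eaf is None:
                decisions.append((exp.variant_id, "dropped", "palindromic, eaf missing"))
                continue
            lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
            if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                decisions.append((exp.variant_id, "dropped", "palindromic, eaf ambiguous"))
                continue
            # same minor/major side on both tables => same allele labelled
            orientation = "unchanged" if (exp.eaf < 0.5) == (out.eaf < 0.5) else "flipped"
        else:
            orientation = _orient_outcome(exp, out)
            if orientation is None:
                decisions.append((exp.variant_id, "dropped", "allele mismatch"))
                continue
        sign = 1.0 if orientation == "unchanged" else -1.0
        rows.append(
            {
                "SNP": exp.variant_id,
                "beta_x": exp.beta,
                "se_x": exp.se,
                "beta_y": sign * out.beta,
                "se_y": out.se,
                "eaf_x": math.nan if exp.eaf is None else exp.eaf,
                "orientation": orientation,
            }
        )
        decisions.append((exp.variant_id, "retained", orientation))
    df = pd.DataFrame(
        rows, columns=["SNP", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "orientation"]
    )
    return HarmonizedTable(df, decisions)


def harmonized_to_tables(
    h: HarmonizedTable,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Re-export a HarmonizedTable as aligned exposure/outcome association lists.

    Both sides come back on the same (arbitrary A/G) allele pair, which makes
    harmonization idempotence directly checkable.
    """
    exp, out = [], []
    for row in h.table.itertuples(index=False):
        eaf = None if math.isnan(row.eaf_x) else row.eaf_x
        for lst, beta, se in ((exp, row.beta_x, row.se_x), (out, row.beta_y, row.se_y)):
            z = beta / se
            p = min(1.0, max(5e-324, 2 * _norm_sf(abs(z))))
            lst.append(
                VariantAssociation(
                    variant_id=row.SNP,
                    effect_allele="A",
                    other_allele="G",
                    beta=beta,
                    se=se,
                    pvalue=p,
                    eaf=eaf,
                )
            )
    return exp, out


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))
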
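"""Per-level gene-set enrichment: one-sided Fisher test with BH FDR.

Each TO-GCN level's co-expressed gene set is tested for over-representation
of every annotation term against the background of all expressed genes.
P-values are upper hypergeometric tails; the FDR is controlled per level
with the Benjamini-Hochberg step-up procedure (a global switch is
available). Rows with FDR < 0.05 constitute the enriched report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "TermCollection",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "fisher_enrichment_per_level",
]


@dataclass(frozen=True)
class TermCollection:
    """Annotation terms: id -> (human-readable name, member gene set)."""

    names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for tid, genes in self.members.items():
            if not genes:
                raise ValueError(f"term {tid!r} has no member genes")

    def __len__(self) -> int:
        return len(self.members)

    def term_ids(self) -> list[str]:
        return list(self.members)


def read_gmt(path: str | Path) -> TermCollection:
    """Parse a GMT file: ``term_id<TAB>description<TAB>gene...`` per line."""
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        tid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if tid in members:
            raise ValueError(f"{path}:{lineno}: duplicate term ID {tid!r}")
        names[tid] = desc
        members[tid] = frozenset(genes)
    if not members:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return TermCollection(names, members)


def write_gmt(terms: TermCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in terms.members:
            genes = "\t".join(sorted(terms.members[tid]))
            fh.write(f"{tid}\t{terms.names.get(tid, tid)}\t{genes}\n")


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # 2x2 table [[a, b], [c, d]]; Haldane 0.5 correction when any cell is 0
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment_per_level(
    sets: Mapping[int, set[str]],
    terms: TermCollection,
    background: Iterable[str],
    *,
    min_term_size: int = 2,
    min_overlap: int = 1,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Over-representation of each term in each level's gene set.

    The one-sided p-value is the upper hypergeometric tail
    ``P(X >= overlap)`` with population = background size, successes =
    term size in background, draws = level-set size. Level sets and term
    sets are intersected with the background first. BH FDR is applied
    within each level across terms (or globally with ``global_fdr``).
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background gene set is empty")
    term_in_bg = {}
    for tid, genes in terms.members.items():
        tb = genes & bg
        if not tb:
            warnings.warn(f"term {tid!r} has no genes in background; skipped", stacklevel=2)
            continue
        if len(tb) < min_term_size:
            continue
        term_in_bg[tid] = tb
    rows = []
    n_bg = len(bg)
    for level in sorted(sets):
        level_set = set(sets[level]) & bg
        n_draw = len(level_set)
        if n_draw == 0:
            warnings.warn(f"level {level} gene set empty after background intersection", stacklevel=2)
            continue
        for tid, tb in term_in_bg.items():
            k = len(level_set & tb)
            if k < min_overlap:
                continue
            n_term = len(tb)
            p = float(hypergeom.sf(k - 1, n_bg, n_term, n_draw))
            oddsr = _odds_ratio(k, n_draw - k, n_term - k, n_bg - n_term - n_draw + k)
            rows.append(
                (level, tid, terms.names.get(tid, tid), k, n_draw, n_term, n_bg, oddsr, min(p, 1.0))
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "level", "term_id", "term_name", "overlap", "set_size",
            "term_size", "background_size", "odds_ratio", "p_value",
        ],
    )
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        return out
    if global_fdr:
        out["fdr"] = bh_adjust(out["p_value"])
    else:
        out["fdr"] = np.nan
        for level, grp in out.groupby("level"):
            out.loc[grp.index, "fdr"] = bh_adjust(grp["p_value"])
    out = out.sort_values(["level", "fdr", "term_id"], kind="stable").reset_index(drop=True)
    return out
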
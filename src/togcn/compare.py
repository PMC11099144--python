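"""Dual-program TO-GCN comparison.

Given the level assignments of the same TF universe in two developmental
programs (A and B), this module computes per-TF level differences
``d = level_A - level_B``, classifies TFs as changed vs not changed by a
1.5 x SD rule on the d distribution, and calls program-specific TFs in a
late level window (default levels 8-11, the keratinization stage): a TF is
B-specific iff it sits in the window in B but not at any window level in A,
and vice versa; TFs in the window in both programs are common. An optional
differential-expression filter keeps only TFs with adjusted p < 0.05 and
|log2 fold change| > 1 from a supplied table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LevelComparison",
    "SpecificTFReport",
    "compute_level_differences",
    "classify_level_shift",
    "find_type_specific_tfs",
    "apply_deg_filter",
    "read_deg_table",
]


def _levels_of(t) -> Mapping[str, int]:
    """Accept a TOGCN or a plain gene -> level mapping."""
    return t.levels if hasattr(t, "levels") else t


@dataclass(frozen=True)
class LevelComparison:
    """Per-TF level differences between two TO-GCNs, with summary stats."""

    table: pd.DataFrame = field(repr=False)  # tf_id, level_a, level_b, d[, shift_class]
    a_only: frozenset[str]
    b_only: frozenset[str]
    threshold: int | None = None

    @property
    def d(self) -> np.ndarray:
        return self.table["d"].to_numpy(dtype=int)

    @property
    def mean_d(self) -> float:
        return float(self.d.mean())

    @property
    def sd_d(self) -> float:
        # population SD, matching the classification rule
        return float(self.d.std(ddof=0))

    def histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.d, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def summary(self) -> dict:
        out = {
            "n_shared": int(len(self.table)),
            "n_a_only": len(self.a_only),
            "n_b_only": len(self.b_only),
            "mean_d": self.mean_d,
            "sd_d": self.sd_d,
            "histogram": {str(k): v for k, v in sorted(self.histogram().items())},
        }
        if self.threshold is not None:
            out["threshold"] = self.threshold
            out["n_changed"] = int((self.table["shift_class"] == "changed").sum())
        return out


def compute_level_differences(t_a, t_b) -> LevelComparison:
    """d = level_A - level_B for every TF leveled in both networks."""
    la, lb = _levels_of(t_a), _levels_of(t_b)
    shared = sorted(set(la) & set(lb))
    if not shared:
        raise ValueError("no shared TFs between the two TO-GCNs")
    table = pd.DataFrame(
        {
            "tf_id": shared,
            "level_a": [la[g] for g in shared],
            "level_b": [lb[g] for g in shared],
        }
    )
    table["d"] = table["level_a"] - table["level_b"]
    return LevelComparison(
        table,
        a_only=frozenset(set(la) - set(lb)),
        b_only=frozenset(set(lb) - set(la)),
    )


def classify_level_shift(c: LevelComparison, multiplier: float = 1.5) -> LevelComparison:
    """Split shared TFs into changed vs not changed by the SD rule.

    The threshold is ``t = ceil(multiplier * popSD(d))`` with a minimum of
    1; a TF is *changed* iff ``|d| >= t``. With d spread similar to the
    source data this yields t = 3, i.e. the "difference >= 3 changed /
    <= 2 not changed" boundary.
    """
    if len(c.table) < 2:
        raise ValueError("need >= 2 shared TFs to classify level shifts")
    sd = c.sd_d
    if sd == 0:
        warnings.warn("d distribution has zero SD; all TFs classified not changed", stacklevel=2)
    t = max(1, math.ceil(multiplier * sd))
    table = c.table.copy()
    table["shift_class"] = np.where(np.abs(table["d"]) >= t, "changed", "not_changed")
    if sd == 0:
        table["shift_class"] = "not_changed"
    return replace(c, table=table, threshold=t)


@dataclass(frozen=True)
class SpecificTFReport:
    """Program-specific and common TFs within a late level window."""

    a_specific: frozenset[str]
    b_specific: frozenset[str]
    common: frozenset[str]
    window: tuple[int, int]
    levels_a: dict[str, int] = field(default_factory=dict, repr=False)
    levels_b: dict[str, int] = field(default_factory=dict, repr=False)
    deg_filtered: dict[str, frozenset[str]] | None = None
    deg_missing: frozenset[str] = frozenset()

    def table(self) -> pd.DataFrame:
        rows = []
        passed = None
        if self.deg_filtered is not None:
            passed = (
                self.deg_filtered["a_specific"]
                | self.deg_filtered["b_specific"]
                | self.deg_filtered["common"]
            )
        for cat, tfs in (
            ("a_specific", self.a_specific),
            ("b_specific", self.b_specific),
            ("common", self.common),
        ):
            for tf in sorted(tfs):
                rows.append(
                    (
                        tf,
                        cat,
                        self.levels_a.get(tf, ""),
                        self.levels_b.get(tf, ""),
                        "" if passed is None else str(tf in passed),
                    )
                )
        return pd.DataFrame(
            rows, columns=["tf_id", "category", "level_a", "level_b", "passed_deg_filter"]
        )


def find_type_specific_tfs(
    t_a,
    t_b,
    window: tuple[int, int] = (8, 11),
    *,
    require_leveled: bool = False,
) -> SpecificTFReport:
    """Call TFs specific to one program within a level window.

    A TF is B-specific iff its level in B lies in ``window`` and it does
    not occupy any window level in A (either leveled outside the window,
    or absent from A's network when ``require_leveled`` is False). The
    A-specific rule is symmetric; TFs in the window in both programs are
    common. The three classes are disjoint.
    """
    lo, hi = window
    if lo > hi or lo < 1:
        raise ValueError(f"invalid level window {window}")
    la, lb = dict(_levels_of(t_a)), dict(_levels_of(t_b))

    def in_window(levels: Mapping[str, int], tf: str) -> bool:
        return tf in levels and lo <= levels[tf] <= hi

    def absent_ok(levels: Mapping[str, int], tf: str) -> bool:
        if tf in levels:
            return not in_window(levels, tf)
        return not require_leveled

    a_spec, b_spec, common = set(), set(), set()
    for tf in set(la) | set(lb):
        a_in, b_in = in_window(la, tf), in_window(lb, tf)
        if a_in and b_in:
            common.add(tf)
        elif a_in and absent_ok(lb, tf):
            a_spec.add(tf)
        elif b_in and absent_ok(la, tf):
            b_spec.add(tf)
    return SpecificTFReport(
        frozenset(a_spec), frozenset(b_spec), frozenset(common), (lo, hi), la, lb
    )


def read_deg_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2fc", "padj"):
        if col not in t.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    if t["gene_id"].duplicated().any():
        dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene in DEG table: {dup!r}")
    if ((t["padj"] < 0) | (t["padj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    return t


def apply_deg_filter(
    report: SpecificTFReport,
    deg: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> SpecificTFReport:
    """Keep TFs that are significant DEGs: padj < padj_max, |log2fc| > lfc_min.

    TFs absent from the table are dropped from the filtered subsets and
    listed in ``deg_missing``.
    """
    sig = set(
        deg.loc[(deg["padj"] < padj_max) & (deg["log2fc"].abs() > lfc_min), "gene_id"]
    )
    known = set(deg["gene_id"])
    all_called = report.a_specific | report.b_specific | report.common
    missing = frozenset(all_called - known)
    if missing:
        warnings.warn(f"{len(missing)} TF(s) absent from DEG table dropped by filter", stacklevel=2)
    filtered = {
        "a_specific": frozenset(report.a_specific & sig),
        "b_specific": frozenset(report.b_specific & sig),
        "common": frozenset(report.common & sig),
    }
    return replace(report, deg_filtered=filtered, deg_missing=missing)
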
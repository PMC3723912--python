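"""Phospho-site collation and differential abundance analysis.

Quantified phospho-peptide occurrences (charge states, missed cleavages,
additional modifications) are collated to the phosphorylation-site level
by summing per-sample abundances over all occurrences of the same site.

Differential sites are then identified with the transform/test/threshold
procedure standard in label-free phospho-proteomics here: abundances are
arcsinh transformed to approximate normality and compared with a
two-tailed t-test for independent samples, while fold changes are ratios
of within-group means on the RAW values.  A site is significantly
differential when p < 0.05 and the fold change exceeds 1.5 in either
direction (> 1.5 or < 1/1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataInconsistencyError, SchemaError

__all__ = [
    "ID_COLUMNS",
    "DifferentialResult",
    "collate_sites",
    "differential_sites",
    "overlap_counts",
]

#: Identification columns expected in an occurrence-level table; remaining
#: columns are treated as per-sample abundances.
ID_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "site_positions",
    "residue",
    "charge",
    "missed_cuts",
    "other_mods",
]

P_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


@dataclass
class DifferentialResult:
    """Differential test outcome for one phospho-site."""

    site_key: str
    fold_change: float  # raw mean(B) / raw mean(A)
    p_value: float
    significant: bool
    direction: str  # up | down | ns
    n_a: int = 0
    n_b: int = 0
    testable: bool = True
    note: str = ""


def _abundance_columns(table: pd.DataFrame) -> list[str]:
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"occurrence table missing column(s): {missing}")
    return [c for c in table.columns if c not in ID_COLUMNS]


def site_key(protein_id: str, site_positions: str) -> str:
    """Canonical site identifier: protein accession + sorted positions."""
    pos = sorted(int(p) for p in str(site_positions).split(";"))
    return f"{protein_id}_" + ";".join(str(p) for p in pos)


def collate_sites(records: pd.DataFrame) -> pd.DataFrame:
    """Sum peptide occurrences to site-level abundance profiles.

    All charge states, missed cleavages and further modifications of the
    same phosphorylation site are summed per sample; total abundance is
    conserved.  Conflicting residue annotations at the same position raise
    :class:`DataInconsistencyError`.

    Returns a frame indexed by ``site_key`` with columns ``protein_id``,
    ``site_positions``, ``residue`` and one column per sample.
    """
    samples = _abundance_columns(records)
    work = records.copy()
    work["site_key"] = [
        site_key(p, s) for p, s in zip(work["protein_id"], work["site_positions"])
    ]

    residue_sets = work.groupby("site_key")["residue"].agg(lambda s: set(s.dropna()))
    conflicts = residue_sets[residue_sets.apply(len) > 1]
    if len(conflicts):
        raise DataInconsistencyError(
            "conflicting residue annotations at site(s): "
            + ", ".join(conflicts.index[:5])
        )

    agg = {c: "sum" for c in samples}
    agg.update({"protein_id": "first", "site_positions": "first", "residue": "first"})
    sites = work.groupby("site_key").agg(agg)
    return sites[["protein_id", "site_positions", "residue"] + samples]


def differential_sites(
    sites: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Test each site for differential abundance between two sample groups.

    ``group_a`` is the control/reference (denominator of the fold change),
    ``group_b`` the comparison group.  The t-test runs on arcsinh-
    transformed abundances; the fold change on raw within-group means.
    Sites with fewer than two finite values in either group, or a zero
    group-A mean, are reported as untestable rather than dropped.
    """
    for col in list(group_a) + list(group_b):
        if col not in sites.columns:
            raise SchemaError(f"sample column {col!r} not in site table")
    A = sites[list(group_a)].to_numpy(dtype=float)
    B = sites[list(group_b)].to_numpy(dtype=float)
    results = []
    for i, key in enumerate(sites.index):
        a = A[i][np.isfinite(A[i])]
        b = B[i][np.isfinite(B[i])]
        if a.size < 2 or b.size < 2:
            results.append(
                DifferentialResult(
                    key, float("nan"), float("nan"), False, "ns",
                    a.size, b.size, testable=False, note="insufficient replicates",
                )
            )
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a == 0.0:
            results.append(
                DifferentialResult(
                    key, float("nan"), float("nan"), False, "ns",
                    a.size, b.size, testable=False, note="zero control mean",
                )
            )
            continue
        fc = mean_b / mean_a
        ta, tb = np.arcsinh(a), np.arcsinh(b)
        if ta.std(ddof=1) == 0.0 and tb.std(ddof=1) == 0.0:
            p = 1.0 if np.isclose(ta.mean(), tb.mean()) else 0.0
        else:
            _, p = stats.ttest_ind(tb, ta, equal_var=equal_var)
            p = float(p)
        sig = (p < p_threshold) and (fc > fc_threshold or fc < 1.0 / fc_threshold)
        if sig:
            direction = "up" if fc > 1.0 else "down"
        else:
            direction = "ns"
        results.append(
            DifferentialResult(key, float(fc), p, bool(sig), direction,
                               a.size, b.size)
        )
    return results


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of differential results with a BH-FDR column.

    The FDR column is informational only; significance gating uses the raw
    p-value and fold-change thresholds.
    """
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("site_key")
    p = df["p_value"].to_numpy()
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = _bh_fdr(p[ok])
    df["fdr_bh"] = q
    return df


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class OverlapSummary:
    """Per-comparison significant counts and pairwise overlaps by direction."""

    counts: dict = field(default_factory=dict)  # name -> {"up": n, "down": n}
    intersections: dict = field(default_factory=dict)
    # (name1, name2, direction) -> shared site count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"comparison_1": a, "comparison_2": b, "direction": d, "count": n}
            for (a, b, d), n in self.intersections.items()
        ]
        return pd.DataFrame(rows)


def overlap_counts(results: Mapping[str, Sequence[DifferentialResult]]) -> OverlapSummary:
    """Count significant sites per comparison and their pairwise overlaps.

    Input maps a comparison name (e.g. inhibitor identity) to its
    differential results; output drives a chord-diagram style summary.
    """
    sets: dict[str, dict[str, set]] = {}
    summary = OverlapSummary()
    for name, results_list in results.items():
        up = {r.site_key for r in results_list if r.significant and r.direction == "up"}
        down = {
            r.site_key for r in results_list if r.significant and r.direction == "down"
        }
        sets[name] = {"up": up, "down": down}
        summary.counts[name] = {"up": len(up), "down": len(down)}
    for a, b in combinations(sets, 2):
        for d in ("up", "down"):
            summary.intersections[(a, b, d)] = len(sets[a][d] & sets[b][d])
    return summary
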
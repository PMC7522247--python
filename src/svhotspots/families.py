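"""Grouping of dependent peaks associated with the same gene into families.

Two peaks associated with one gene are "dependent" when the samples
harboring their SVs overlap more than chance — a one-sided Fisher's exact
(hypergeometric) test on the 2x2 sample membership table. Dependent peaks
likely reflect the same underlying rearrangements; connected components of
the dependency graph become peak families, represented by the member with
the highest sample count (ties to the leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .detection import Peak


@dataclass
class PeakFamily:
    gene: str
    members: list[str]          # peak ids, coordinate order
    representative: str


def test_dependency(
    samples_a: set[str], samples_b: set[str], cohort: set[str]
) -> float:
    """One-sided (enrichment) Fisher's exact p for sample-set overlap."""
    if not cohort:
        raise ValueError("empty cohort")
    a, b = samples_a & cohort, samples_b & cohort
    both = len(a & b)
    only_a = len(a) - both
    only_b = len(b) - both
    neither = len(cohort) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def build_families(
    significant_pairs: Sequence[tuple[str, str]],
    peaks: Mapping[str, Peak],
    cohort: set[str],
    alpha_dep: float = 0.05,
) -> list[PeakFamily]:
    """Build per-gene peak families from significant (peak_id, gene) pairs.

    For each gene, edges connect peak pairs with dependency p < alpha_dep;
    connected components of size >= 2 are reported as families (singletons
    remain standalone peaks and are not listed).
    """
    by_gene: dict[str, list[str]] = {}
    for peak_id, gene in significant_pairs:
        if peak_id not in by_gene.setdefault(gene, []):
            by_gene[gene].append(peak_id)
    families: list[PeakFamily] = []
    for gene in sorted(by_gene):
        ids = sorted(by_gene[gene], key=lambda pid: (peaks[pid].chrom, peaks[pid].start))
        parent = {pid: pid for pid in ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, pa in enumerate(ids):
            for pb in ids[i + 1:]:
                p = test_dependency(peaks[pa].samples, peaks[pb].samples, cohort)
                if p < alpha_dep:
                    parent[find(pa)] = find(pb)
        components: dict[str, list[str]] = {}
        for pid in ids:
            components.setdefault(find(pid), []).append(pid)
        for comp in components.values():
            if len(comp) < 2:
                continue
            rep = max(comp, key=lambda pid: (peaks[pid].count, -peaks[pid].start))
            families.append(PeakFamily(gene, comp, rep))
    return families


def families_table(families: Sequence[PeakFamily], peaks: Mapping[str, Peak]):
    import pandas as pd

    rows = [
        {
            "gene": f.gene,
            "members": "|".join(f.members),
            "representative": f.representative,
            "member_counts": "|".join(str(peaks[m].count) for m in f.members),
        }
        for f in families
    ]
    return pd.DataFrame(rows)
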
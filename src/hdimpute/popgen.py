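"""Population-genetic metrics: LD decay from phased haplotypes, pedigree
additive relationships, and the effective number of ancestors.

r² between two loci A and B is the squared correlation of alleles on
haplotypes,

    r² = (p_A1B1 - p_A1 p_B1)² / (p_A1 p_A2 p_B1 p_B2),

with all frequencies counted over the phased haplotype panel. Pairs in
which either marker has MAF below a cutoff (default 5%) are discarded
before averaging r² by inter-marker distance, and the decay curve is
summarized by the mean r² in the bin containing 70 kb — roughly the
spacing of informative markers on a medium-density cattle chip.

The additive (numerator) relationship is Wright's coefficient computed by
the recursive tabular method; the training/validation relationship
R_T/V is its mean over all cross pairs. The effective number of ancestors
follows the probability-of-gene-origin approach: ancestors are picked
greedily by marginal expected contribution to the reference set (blocking
gene flow through previously selected ancestors), and
N_a = 1 / sum(marginal contribution²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import UNKNOWN_PARENT, HaplotypePanel, MarkerMap, Pedigree


def compute_r2(h: HaplotypePanel, marker_a: str, marker_b: str) -> float:
    """Haplotype-frequency r² between two markers of a phased panel."""
    idx = {m: i for i, m in enumerate(h.marker_ids)}
    for m in (marker_a, marker_b):
        if m not in idx:
            raise KeyError(f"marker not in panel: {m}")
    a = h.alleles[:, idx[marker_a]].astype(float)
    b = h.alleles[:, idx[marker_b]].astype(float)
    return _r2_columns(a, b)


def _r2_columns(a: np.ndarray, b: np.ndarray) -> float:
    p_a1 = a.mean()
    p_b1 = b.mean()
    if p_a1 in (0.0, 1.0) or p_b1 in (0.0, 1.0):
        raise ValueError("r2 undefined for a monomorphic marker")
    p_ab = (a * b).mean()
    d = p_ab - p_a1 * p_b1
    return float(d * d / (p_a1 * (1 - p_a1) * p_b1 * (1 - p_b1)))


@dataclass
class LDDecayCurve:
    bin_edges_bp: np.ndarray  # length n_bins + 1
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_bp": self.bin_edges_bp[:-1],
                "bin_end_bp": self.bin_edges_bp[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )


def ld_decay(
    h: HaplotypePanel,
    marker_map: MarkerMap,
    maf_min: float = 0.05,
    bin_width_bp: int = 10_000,
    max_dist_bp: int = 200_000,
    chromosomes=None,
) -> LDDecayCurve:
    """Mean r² binned by distance over intra-chromosome marker pairs.

    The MAF filter is applied pairwise: a pair enters no bin if either
    marker's MAF is below ``maf_min``.
    """
    mmap = marker_map.subset(h.marker_ids)
    if not np.array_equal(mmap.marker_ids, h.marker_ids):
        h = h.subset(markers=mmap.marker_ids)
    freqs = h.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    eligible = maf >= maf_min
    chroms = mmap.chromosomes
    pos = mmap.positions_bp
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    wanted = set(chromosomes) if chromosomes is not None else None
    X = h.alleles.astype(np.float64)
    for chrom in np.unique(chroms):
        if wanted is not None and chrom not in wanted:
            continue
        cols = np.flatnonzero((chroms == chrom) & eligible)
        if len(cols) < 2:
            continue
        cpos = pos[cols]
        Z = X[:, cols]
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        n_hap = Z.shape[0]
        for i in range(len(cols) - 1):
            j_hi = np.searchsorted(cpos, cpos[i] + max_dist_bp, side="right")
            if j_hi <= i + 1:
                continue
            d = cpos[i + 1 : j_hi] - cpos[i]
            r = Z[:, i] @ Z[:, i + 1 : j_hi] / n_hap
            b = np.minimum((d // bin_width_bp).astype(int), n_bins - 1)
            np.add.at(sums, b, r * r)
            np.add.at(counts, b, 1)
    if counts.sum() == 0:
        raise ValueError("no eligible marker pairs for LD computation")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width_bp
    return LDDecayCurve(edges, mean_r2, counts)


def ld_at(curve: LDDecayCurve, distance_bp: int = 70_000) -> float:
    """Mean r² of the distance bin containing ``distance_bp``."""
    b = np.searchsorted(curve.bin_edges_bp, distance_bp, side="right") - 1
    if b < 0 or b >= len(curve.mean_r2):
        raise ValueError(f"distance {distance_bp} outside curve range")
    if curve.pair_counts[b] == 0:
        raise ValueError(f"no marker pairs in the bin containing {distance_bp} bp")
    return float(curve.mean_r2[b])


def additive_relationship(ped: Pedigree, pairs=None) -> np.ndarray | dict:
    """Wright's numerator relationship matrix by the tabular method.

    Returns the full matrix in pedigree row order, or, if ``pairs`` is
    given as (id, id) tuples, a dict mapping each pair to its coefficient.
    """
    ids = ped.animal_ids
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    order = ped.topological_order()
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    sires = ped.table["sire_id"].to_numpy()
    dams = ped.table["dam_id"].to_numpy()
    A = np.zeros((n, n))
    for i in order:
        s = idx[sires[i]] if sires[i] != UNKNOWN_PARENT else -1
        d = idx[dams[i]] if dams[i] != UNKNOWN_PARENT else -1
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        earlier = order[: rank[i]]
        if len(earlier):
            row = np.zeros(len(earlier))
            if s >= 0:
                row += 0.5 * A[s, earlier]
            if d >= 0:
                row += 0.5 * A[d, earlier]
            A[i, earlier] = row
            A[earlier, i] = row
    if pairs is None:
        return A
    return {(a, b): float(A[idx[a], idx[b]]) for a, b in pairs}


@dataclass
class RelationshipSummary:
    mean_r_tv: float
    n_pairs: int


def mean_cross_relationship(ped: Pedigree, training_ids, validation_ids) -> RelationshipSummary:
    """Mean additive relationship over all (training, validation) pairs."""
    t = list(training_ids)
    v = list(validation_ids)
    if not t or not v:
        raise ValueError("training and validation sets must be non-empty")
    if set(t) & set(v):
        raise ValueError("training and validation sets overlap")
    A = additive_relationship(ped)
    idx = {a: i for i, a in enumerate(ped.animal_ids)}
    ti = np.array([idx[a] for a in t])
    vi = np.array([idx[a] for a in v])
    block = A[np.ix_(ti, vi)]
    return RelationshipSummary(mean_r_tv=float(block.mean()), n_pairs=block.size)


@dataclass
class EffectiveAncestorsResult:
    n_effective_ancestors: float
    contributions: list  # (animal_id, marginal contribution), selection order


def effective_ancestors(
    ped: Pedigree, reference_ids, max_ancestors: int | None = None, tol: float = 1e-9
) -> EffectiveAncestorsResult:
    """Greedy probability-of-gene-origin ancestor selection.

    At each round the expected gene flow from the reference set is
    propagated up the pedigree, blocked at already-selected ancestors.
    The flow arriving at a candidate is further multiplied by the fraction
    of the candidate's own genome not yet explained by selected ancestors
    (a candidate that is itself a descendant of a selected ancestor can
    only add its non-inherited share); the candidate with the largest
    corrected marginal contribution is selected each round.
    """
    refs = list(reference_ids)
    if not refs:
        raise ValueError("reference set is empty")
    ids = ped.animal_ids
    idx = {a: i for i, a in enumerate(ids)}
    for r in refs:
        if r not in idx:
            raise KeyError(f"reference animal not in pedigree: {r}")
    n = len(ids)
    sires = ped.table["sire_id"].to_numpy()
    dams = ped.table["dam_id"].to_numpy()
    order = ped.topological_order()  # parents before offspring
    youngest_first = order[::-1]
    base = np.zeros(n)
    for r in refs:
        base[idx[r]] += 1.0 / len(refs)
    selected: list[int] = []
    contributions: list[tuple[str, float]] = []
    limit = max_ancestors if max_ancestors is not None else n
    explained = 0.0
    sel_mask = np.zeros(n, dtype=bool)
    while len(selected) < limit and explained < 1.0 - tol:
        # upward pass: expected reference gene flow, captured at selected
        flow = base.copy()
        arrived = np.zeros(n)
        for i in youngest_first:
            arrived[i] += flow[i]
            if sel_mask[i]:
                continue  # gene captured by a selected ancestor: stop here
            s = idx[sires[i]] if sires[i] != UNKNOWN_PARENT else -1
            d = idx[dams[i]] if dams[i] != UNKNOWN_PARENT else -1
            if s >= 0:
                flow[s] += 0.5 * flow[i]
            if d >= 0:
                flow[d] += 0.5 * flow[i]
            # share with no known parent originates at this animal
        # downward pass: fraction of each genome explained by selected
        expl = np.zeros(n)
        for i in order:
            if sel_mask[i]:
                expl[i] = 1.0
                continue
            s = idx[sires[i]] if sires[i] != UNKNOWN_PARENT else -1
            d = idx[dams[i]] if dams[i] != UNKNOWN_PARENT else -1
            expl[i] = (0.5 * expl[s] if s >= 0 else 0.0) + (0.5 * expl[d] if d >= 0 else 0.0)
        marginal = arrived * (1.0 - expl)
        marginal[sel_mask] = -1.0
        best = int(np.argmax(marginal))
        if marginal[best] <= tol:
            break
        sel_mask[best] = True
        selected.append(best)
        contributions.append((str(ids[best]), float(marginal[best])))
        explained += float(marginal[best])
    marginals = np.array([c for _, c in contributions])
    n_a = float(1.0 / np.sum(marginals**2))
    return EffectiveAncestorsResult(n_effective_ancestors=n_a, contributions=contributions)
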
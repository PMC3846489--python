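"""Haplotype-copying imputation (Li-Stephens-style HMM).

The reference panel is phased by iterative conditional phasing: starting
from a random het orientation, each animal is re-phased against the current
haplotypes of all other animals, repeatedly, with a greedy two-chain HMM
pass whose direction alternates between iterations. Targets genotyped on
the reduced (shared) marker set are then imputed per haploid chain by
forward-backward over the reference haplotypes; the two chain posteriors
are combined independently into genotype posteriors and expected dosages.

Template switching between adjacent markers occurs with probability
``1 - exp(-recomb_rate_per_bp * d)`` (``d`` the inter-marker distance in
bp), shared uniformly across templates; the default rate of 1e-8/bp equals
the 1 cM/Mb genetic map used by the gene-drop simulator. No pedigree
information is used at any point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .model import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap
from ._kernels import (
    diploid_viterbi_orientation,
    forward_backward_alleles,
)

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    copy_error: float = 0.001
    recomb_rate_per_bp: float = 1e-8
    n_phasing_iterations: int = 20
    n_surrogates: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.copy_error < 1):
            raise ValueError("copy_error must be in (0, 1)")
        if self.recomb_rate_per_bp <= 0:
            raise ValueError("recomb_rate_per_bp must be positive")
        if self.n_phasing_iterations < 1:
            raise ValueError("n_phasing_iterations must be >= 1")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


@dataclass
class ImputedGenotypes:
    hard_calls: GenotypeMatrix
    dosages: np.ndarray  # (n_animals, n_markers) expected alt-allele count
    posterior_max: np.ndarray  # (n_animals, n_markers) max genotype posterior


def _switch_probs(mmap: MarkerMap, rate: float) -> np.ndarray:
    """Per-marker switch probability from the previous marker.

    Chromosome starts get probability 1 (the chain re-draws its template
    uniformly: chromosomes are unlinked); index 0 is unused.
    """
    pos = mmap.positions_bp.astype(np.float64)
    chrom = mmap.chromosomes
    rho = np.zeros(len(pos))
    rho[1:] = 1.0 - np.exp(-rate * np.abs(np.diff(pos)))
    starts = np.r_[True, np.diff(chrom) != 0]
    rho[starts] = 1.0
    rho[0] = 0.0
    return rho


def _frame_switch_probs(pos: np.ndarray, chrom: np.ndarray, rate: float) -> np.ndarray:
    """Switch probabilities for an arbitrary ordered marker subset."""
    rho = np.zeros(len(pos))
    if len(pos) > 1:
        rho[1:] = 1.0 - np.exp(-rate * np.abs(np.diff(pos.astype(np.float64))))
        rho[np.r_[False, np.diff(chrom) != 0]] = 1.0
    return rho


class HaplotypeCopyingImputer(BaseEstimator):
    """Impute masked high-density genotypes from a phased reference panel.

    Parameters
    ----------
    copy_error : float
        Emission mismatch probability of the copying model.
    recomb_rate_per_bp : float
        Template-switch rate per base pair (default 1e-8 = 1 cM/Mb).
    n_phasing_iterations : int
        Conditional-phasing sweeps over the reference panel.
    seed : int
        Seed for the random phasing start and sweep order.

    Attributes
    ----------
    reference_ : HaplotypePanel
        The phased reference panel (phased during ``fit`` when genotypes
        are supplied).
    marker_map_ : MarkerMap
        Map restricted to the reference markers.
    """

    def __init__(
        self,
        copy_error: float = 0.001,
        recomb_rate_per_bp: float = 1e-8,
        n_phasing_iterations: int = 20,
        n_surrogates: int = 20,
        seed: int = 0,
    ):
        self.copy_error = copy_error
        self.recomb_rate_per_bp = recomb_rate_per_bp
        self.n_phasing_iterations = n_phasing_iterations
        self.n_surrogates = n_surrogates
        self.seed = seed

    def _config(self) -> ImputationConfig:
        cfg = ImputationConfig(
            copy_error=self.copy_error,
            recomb_rate_per_bp=self.recomb_rate_per_bp,
            n_phasing_iterations=self.n_phasing_iterations,
            n_surrogates=self.n_surrogates,
            seed=self.seed,
        )
        cfg.validate()
        return cfg

    def fit(self, X, marker_map: MarkerMap):
        """Set (and if necessary phase) the reference panel.

        ``X`` may be a ``HaplotypePanel`` (already phased) or a
        ``GenotypeMatrix`` to be phased in place.
        """
        cfg = self._config()
        if isinstance(X, HaplotypePanel):
            panel = X
        elif isinstance(X, GenotypeMatrix):
            panel = self._phase(X, marker_map, cfg)
        else:
            raise TypeError("X must be a HaplotypePanel or GenotypeMatrix")
        if panel.n_haplotypes == 0:
            raise ValueError("reference panel has zero haplotypes")
        self.marker_map_ = marker_map.subset(panel.marker_ids)
        if not np.array_equal(self.marker_map_.marker_ids, panel.marker_ids):
            panel = panel.subset(markers=self.marker_map_.marker_ids)
        self.reference_ = panel
        return self

    def _phase(self, g: GenotypeMatrix, marker_map: MarkerMap, cfg: ImputationConfig) -> HaplotypePanel:
        mmap = marker_map.subset(g.marker_ids)
        g = g.subset(markers=mmap.marker_ids)
        rng = np.random.default_rng(cfg.seed)
        n, m = g.n_animals, g.n_markers
        if n < 1:
            raise ValueError("cannot phase an empty panel")
        freqs = np.nan_to_num(g.alt_allele_frequency(), nan=0.5)
        H = np.empty((2 * n, m), dtype=np.int8)
        calls = g.calls
        for i in range(n):
            row = calls[i]
            a1 = np.where(row == 2, 1, 0).astype(np.int8)
            a2 = a1.copy()
            het = row == 1
            flip = rng.random(het.sum()) < 0.5
            idx_het = np.flatnonzero(het)
            a1[idx_het] = np.where(flip, 1, 0)
            a2[idx_het] = 1 - a1[idx_het]
            miss = np.flatnonzero(row == MISSING)
            a1[miss] = rng.random(len(miss)) < freqs[miss]
            a2[miss] = rng.random(len(miss)) < freqs[miss]
            H[2 * i] = a1
            H[2 * i + 1] = a2
        if n == 1:
            logger.warning("single-animal panel: het orientation is arbitrary")
            return HaplotypePanel(g.animal_ids.copy(), mmap.marker_ids, H)
        rho = _switch_probs(mmap, cfg.recomb_rate_per_bp)
        obs = np.ascontiguousarray(calls)
        # surrogate panel per animal: its most IBS-similar animals carry the
        # closest haplotypes (parents, progeny, sibs), so a small diploid
        # Viterbi against them phases each animal almost exactly
        n_surrogates = min(cfg.n_surrogates, n - 1)
        G = calls.astype(np.float64)
        G[calls == MISSING] = 1.0
        sq = (G * G).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (G @ G.T)
        np.fill_diagonal(d2, np.inf)
        nearest = np.argsort(d2, axis=1)[:, :n_surrogates]
        o1 = np.zeros(m, dtype=np.int8)
        o2 = np.zeros(m, dtype=np.int8)
        # progressive build-up: phase each animal against the already-phased
        # subset only, so the panel never has to escape a frustrated random
        # start; the sweeps below then refine against full surrogate sets
        build_order = rng.permutation(n)
        phased: list[int] = [int(build_order[0])]
        for i in build_order[1:]:
            done = np.asarray(phased)
            pick = done[np.argsort(d2[i, done])[: min(n_surrogates, len(done))]]
            rows = np.empty(2 * len(pick), dtype=np.int64)
            rows[0::2] = 2 * pick
            rows[1::2] = 2 * pick + 1
            Hsub = np.ascontiguousarray(H[rows])
            diploid_viterbi_orientation(Hsub, obs[i], rho, cfg.copy_error, o1, o2)
            H[2 * i] = o1
            H[2 * i + 1] = o2
            phased.append(int(i))
        # animals are re-phased only while their own assignment or a
        # surrogate's changed in the previous sweep
        users_of: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for s in nearest[i]:
                users_of[s].append(i)
        dirty = np.ones(n, dtype=bool)
        prev_changed = None
        for it in range(cfg.n_phasing_iterations):
            order = rng.permutation(n)
            changed_total = 0
            next_dirty = np.zeros(n, dtype=bool)
            for i in order:
                if not dirty[i]:
                    continue
                rows = np.empty(2 * n_surrogates, dtype=np.int64)
                rows[0::2] = 2 * nearest[i]
                rows[1::2] = 2 * nearest[i] + 1
                Hsub = np.ascontiguousarray(H[rows])
                diploid_viterbi_orientation(Hsub, obs[i], rho, cfg.copy_error, o1, o2)
                delta = int((H[2 * i] != o1).sum() + (H[2 * i + 1] != o2).sum())
                if delta:
                    H[2 * i] = o1
                    H[2 * i + 1] = o2
                    changed_total += delta
                    next_dirty[i] = True
                    next_dirty[users_of[i]] = True
            dirty = next_dirty
            # stop at convergence or when a sweep stops making real
            # progress (residual flicker between near-equivalent phasings)
            if changed_total <= n:
                break
            if prev_changed is not None and changed_total > 0.5 * prev_changed:
                break
            prev_changed = changed_total
        return HaplotypePanel(g.animal_ids.copy(), mmap.marker_ids, H)

    def predict(self, X: GenotypeMatrix) -> ImputedGenotypes:
        """Impute every marker of the reference map for the target animals.

        Target markers must be a subset of the reference markers; masked or
        untyped markers carry ``MISSING`` and receive posterior dosages,
        while observed hard calls are passed through unchanged.
        """
        if not hasattr(self, "reference_"):
            raise RuntimeError("imputer is not fitted")
        cfg = self._config()
        ref = self.reference_
        mmap = self.marker_map_
        known = set(ref.marker_ids)
        extra = [m for m in X.marker_ids if m not in known]
        if extra:
            raise KeyError(f"target markers absent from reference map: {extra[:5]}")
        m = len(ref.marker_ids)
        n = X.n_animals
        # expand target calls onto the full reference marker frame
        col_of = {mid: j for j, mid in enumerate(ref.marker_ids)}
        calls_full = np.full((n, m), MISSING, dtype=np.int8)
        src_cols = np.array([col_of[mid] for mid in X.marker_ids], dtype=np.int64)
        calls_full[:, src_cols] = X.calls
        rho = _switch_probs(mmap, cfg.recomb_rate_per_bp)
        H = np.ascontiguousarray(ref.alleles)
        ce = cfg.copy_error
        dosages = np.zeros((n, m))
        post_max = np.zeros((n, m))
        hard = np.zeros((n, m), dtype=np.int8)
        positions = mmap.positions_bp
        chroms = mmap.chromosomes
        # orientation subpanel: the reference animals most IBS-similar to
        # each target on the observed markers (the haploid smoothing below
        # still uses the full panel)
        n_ref_animals = len(ref.animal_ids)
        n_orient = min(2 * cfg.n_surrogates, n_ref_animals)
        ref_genos = H[0::2].astype(np.float64) + H[1::2].astype(np.float64)
        for i in range(n):
            g_row = np.ascontiguousarray(calls_full[i])
            obs1 = np.full(m, -1, dtype=np.int8)
            obs2 = np.full(m, -1, dtype=np.int8)
            obs_cols = np.flatnonzero(g_row != MISSING)
            if len(obs_cols):
                d2 = ((ref_genos[:, obs_cols] - g_row[obs_cols].astype(np.float64)) ** 2).sum(axis=1)
                near = np.argsort(d2)[:n_orient]
                rows = np.empty(2 * n_orient, dtype=np.int64)
                rows[0::2] = 2 * near
                rows[1::2] = 2 * near + 1
                # diploid Viterbi on the observed frame phases the
                # heterozygous sites jointly
                Hobs = np.ascontiguousarray(H[np.ix_(rows, obs_cols)])
                rho_obs = _frame_switch_probs(
                    positions[obs_cols], chroms[obs_cols], cfg.recomb_rate_per_bp
                )
                o1 = np.zeros(len(obs_cols), dtype=np.int8)
                o2 = np.zeros(len(obs_cols), dtype=np.int8)
                diploid_viterbi_orientation(Hobs, g_row[obs_cols], rho_obs, ce, o1, o2)
                obs1[obs_cols] = o1
                obs2[obs_cols] = o2
            p1 = forward_backward_alleles(H, -1, -1, obs1, rho, ce)
            p2 = forward_backward_alleles(H, -1, -1, obs2, rho, ce)
            g0 = (1 - p1) * (1 - p2)
            g1 = p1 * (1 - p2) + p2 * (1 - p1)
            g2 = p1 * p2
            post = np.stack((g0, g1, g2))
            call = post.argmax(axis=0).astype(np.int8)
            observed = g_row != MISSING
            call[observed] = g_row[observed]
            dose = p1 + p2
            dose[observed] = g_row[observed]
            hard[i] = call
            dosages[i] = dose
            post_max[i] = post.max(axis=0)
            post_max[i, observed] = 1.0
        return ImputedGenotypes(
            hard_calls=GenotypeMatrix(X.animal_ids.copy(), ref.marker_ids.copy(), hard),
            dosages=dosages,
            posterior_max=post_max,
        )

    # transform is an alias so the estimator drops into sklearn pipelines
    transform = predict


def phase_reference(g: GenotypeMatrix, marker_map: MarkerMap, cfg: ImputationConfig | None = None) -> HaplotypePanel:
    """Phase a genotype panel; thin wrapper over ``HaplotypeCopyingImputer``."""
    cfg = cfg or ImputationConfig()
    imp = HaplotypeCopyingImputer(**cfg.__dict__)
    imp.fit(g, marker_map)
    return imp.reference_


def impute_target(
    ref: HaplotypePanel,
    target: GenotypeMatrix,
    marker_map: MarkerMap,
    cfg: ImputationConfig | None = None,
) -> ImputedGenotypes:
    """Impute targets against a phased reference panel."""
    cfg = cfg or ImputationConfig()
    imp = HaplotypeCopyingImputer(**cfg.__dict__)
    imp.fit(ref, marker_map)
    return imp.predict(target)
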
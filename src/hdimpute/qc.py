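"""SNP-array data-editing cascade.

The editing rules reproduce routine cattle-chip quality control: animals
with call rate below 0.95 are removed; markers are dropped for
Hardy-Weinberg disequilibrium (exact test, p < 0.001) or more than 10%
missing calls; markers discordant in more than 1% of animals genotyped on
both chips are excluded; parentage is verified on 500 informative markers
(an opposing-homozygote count above 10 flags a pair); and residual
Mendelian conflicts are repaired by blanking either the sire's call (when
more than 20% of his progeny contradict him at a marker) or the
conflicting progeny calls. All thresholds are strict inequalities. The
cascade order is fixed (animals, markers, concordance, parentage,
Mendelian repair) and the report it emits fully determines the edited
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import MISSING, UNKNOWN_PARENT, GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_animal_call_rate: float = 0.95
    hwe_p_threshold: float = 0.001
    max_snp_missing: float = 0.10
    max_discordance: float = 0.01
    n_parentage_markers: int = 500
    max_incompatibilities: int = 10
    max_progeny_contradiction: float = 0.20

    def validate(self) -> None:
        for name in ("min_animal_call_rate", "hwe_p_threshold", "max_snp_missing", "max_discordance", "max_progeny_contradiction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_parentage_markers < 1 or self.max_incompatibilities < 0:
            raise ValueError("invalid parentage test configuration")


@dataclass
class QCReport:
    """Removals and per-call edits; replaying it reproduces the edited data."""

    removed_animals: list = field(default_factory=list)  # (animal_id, reason)
    removed_markers: list = field(default_factory=list)  # (marker_id, reason)
    genotype_edits: list = field(default_factory=list)  # (animal_id, marker_id, action)

    def extend(self, other: "QCReport") -> None:
        self.removed_animals.extend(other.removed_animals)
        self.removed_markers.extend(other.removed_markers)
        self.genotype_edits.extend(other.genotype_edits)

    def apply(self, g: GenotypeMatrix) -> GenotypeMatrix:
        """Replay removals and edits on the raw input matrix."""
        drop_a = {a for a, _ in self.removed_animals}
        drop_m = {m for m, _ in self.removed_markers}
        keep_a = [a for a in g.animal_ids if a not in drop_a]
        keep_m = [m for m in g.marker_ids if m not in drop_m]
        out = g.subset(animals=keep_a, markers=keep_m)
        ai = {a: i for i, a in enumerate(out.animal_ids)}
        mi = {m: j for j, m in enumerate(out.marker_ids)}
        for animal, marker, action in self.genotype_edits:
            if action == "set_missing" and animal in ai and marker in mi:
                out.calls[ai[animal], mi[marker]] = MISSING
        return out


def filter_animals_by_call_rate(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Remove animals whose call rate is strictly below the threshold."""
    cfg.validate()
    rates = g.call_rate_per_animal()
    keep = rates >= cfg.min_animal_call_rate
    report = QCReport(removed_animals=[(str(a), "call_rate") for a in g.animal_ids[~keep]])
    if keep.all():
        return g, report
    return g.subset(animals=list(g.animal_ids[keep])), report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one. Monomorphic markers return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped animal required")
    rare = n_Aa + 2 * min(n_AA, n_aa)  # minor-allele copies
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logw = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_markers(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers failing HWE (p < threshold) or exceeding the missing cap.

    Both criteria are evaluated against the same input state; a marker
    failing both is reported with the missingness reason.
    """
    cfg.validate()
    report = QCReport()
    miss = g.missing_fraction_per_marker()
    keep = np.ones(g.n_markers, dtype=bool)
    for j, mid in enumerate(g.marker_ids):
        if miss[j] > cfg.max_snp_missing:
            keep[j] = False
            report.removed_markers.append((str(mid), "missingness"))
            continue
        col = g.calls[:, j]
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if n_aa + n_het + n_AA == 0:
            keep[j] = False
            report.removed_markers.append((str(mid), "missingness"))
            continue
        if hwe_exact_test(n_AA, n_het, n_aa) < cfg.hwe_p_threshold:
            keep[j] = False
            report.removed_markers.append((str(mid), "hwe"))
    if keep.all():
        return g, report
    return g.subset(markers=list(g.marker_ids[keep])), report


def cross_chip_concordance(hd: GenotypeMatrix, k50: GenotypeMatrix, cfg: QCConfig) -> QCReport:
    """Flag shared markers discordant in more than ``max_discordance`` of
    dual-genotyped animals (both calls non-missing)."""
    cfg.validate()
    shared_animals = [a for a in hd.animal_ids if a in set(k50.animal_ids)]
    shared_markers = [m for m in k50.marker_ids if m in set(hd.marker_ids)]
    if not shared_animals or not shared_markers:
        raise ValueError("concordance check needs dual-genotyped animals and shared markers")
    a_hd = hd.subset(animals=shared_animals, markers=shared_markers)
    a_50 = k50.subset(animals=shared_animals, markers=shared_markers)
    both = (a_hd.calls != MISSING) & (a_50.calls != MISSING)
    n = both.sum(axis=0)
    disc = ((a_hd.calls != a_50.calls) & both).sum(axis=0)
    report = QCReport()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, disc / np.maximum(n, 1), 0.0)
    for j, mid in enumerate(shared_markers):
        if frac[j] > cfg.max_discordance:
            report.removed_markers.append((str(mid), "chip_discordance"))
    return report


def _genotyped_pairs(g: GenotypeMatrix, ped: Pedigree):
    """(offspring, parent, parent_role) pairs with both animals genotyped."""
    genotyped = set(g.animal_ids)
    pairs = []
    for _, row in ped.table.iterrows():
        child = row["animal_id"]
        if child not in genotyped:
            continue
        for role, parent in (("sire", row["sire_id"]), ("dam", row["dam_id"])):
            if parent != UNKNOWN_PARENT and parent in genotyped:
                pairs.append((child, parent, role))
    return pairs


def select_parentage_markers(g: GenotypeMatrix, animal_ids, n_markers: int) -> list[str]:
    """Most informative markers: complete calls in the tested animals,
    ranked by MAF descending, ties broken by map (column) order."""
    sub = g.subset(animals=list(animal_ids))
    complete = (sub.calls != MISSING).all(axis=0)
    maf = sub.minor_allele_frequency()
    candidates = [(float(-maf[j]), j) for j in np.flatnonzero(complete)]
    candidates.sort()
    if len(candidates) < n_markers:
        logger.warning(
            "only %d informative markers available (requested %d)", len(candidates), n_markers
        )
    return [str(g.marker_ids[j]) for _, j in candidates[:n_markers]]


def parentage_test(g: GenotypeMatrix, ped: Pedigree, cfg: QCConfig) -> QCReport:
    """Opposing-homozygote parentage verification.

    A pair with more than ``max_incompatibilities`` opposing homozygotes on
    the informative marker set is flagged; flagged offspring are removed
    unless at least two progeny of the same sire are flagged, in which case
    the sire is removed and those progeny retained.
    """
    cfg.validate()
    pairs = _genotyped_pairs(g, ped)
    if not pairs:
        raise ValueError("no genotyped parent-offspring pairs to test")
    tested_animals = sorted({a for p in pairs for a in (p[0], p[1])})
    markers = select_parentage_markers(g, tested_animals, cfg.n_parentage_markers)
    sub = g.subset(animals=tested_animals, markers=markers)
    ai = {a: i for i, a in enumerate(sub.animal_ids)}
    flagged = []  # (child, parent, role, n_incompat)
    for child, parent, role in pairs:
        c = sub.calls[ai[child]]
        p = sub.calls[ai[parent]]
        opposing = int((((c == 0) & (p == 2)) | ((c == 2) & (p == 0))).sum())
        if opposing > cfg.max_incompatibilities:
            flagged.append((child, parent, role, opposing))
    report = QCReport()
    by_sire: dict[str, list[str]] = {}
    for child, parent, role, _ in flagged:
        if role == "sire":
            by_sire.setdefault(parent, []).append(child)
    removed_sires = {s for s, kids in by_sire.items() if len(kids) >= 2}
    removed = set()
    for sire in sorted(removed_sires):
        report.removed_animals.append((str(sire), "parentage_sire"))
        removed.add(sire)
    for child, parent, role, _ in flagged:
        if role == "sire" and parent in removed_sires:
            continue  # sire removed instead; progeny retained
        if child not in removed:
            report.removed_animals.append((str(child), "parentage"))
            removed.add(child)
    return report


def mendelian_repair(g: GenotypeMatrix, ped: Pedigree, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Blank residual opposing-homozygote conflicts marker by marker.

    For each genotyped parent and marker: if the fraction of its genotyped
    progeny in conflict exceeds ``max_progeny_contradiction``, the parent's
    call is blanked; otherwise each conflicting progeny call is blanked.
    Conflicts are assessed on the input state and all edits applied at once.
    """
    cfg.validate()
    report = QCReport()
    ai = {a: i for i, a in enumerate(g.animal_ids)}
    progeny_of: dict[str, list[str]] = {}
    for child, parent, _role in _genotyped_pairs(g, ped):
        progeny_of.setdefault(parent, []).append(child)
    edits = set()
    for parent, children in progeny_of.items():
        p_row = g.calls[ai[parent]]
        c_rows = g.calls[[ai[c] for c in children]]
        parent_hom0 = p_row == 0
        parent_hom2 = p_row == 2
        conflict = (parent_hom0[None, :] & (c_rows == 2)) | (parent_hom2[None, :] & (c_rows == 0))
        genotyped = c_rows != MISSING
        n_gen = genotyped.sum(axis=0)
        n_conf = conflict.sum(axis=0)
        for j in np.flatnonzero(n_conf > 0):
            if n_conf[j] / n_gen[j] > cfg.max_progeny_contradiction:
                edits.add((parent, str(g.marker_ids[j])))
            else:
                for k in np.flatnonzero(conflict[:, j]):
                    edits.add((children[k], str(g.marker_ids[j])))
    out = g.copy()
    mi = {m: j for j, m in enumerate(out.marker_ids)}
    for animal, marker in sorted(edits):
        out.calls[ai[animal], mi[marker]] = MISSING
        report.genotype_edits.append((str(animal), marker, "set_missing"))
    return out, report


def run_qc(
    hd: GenotypeMatrix,
    ped: Pedigree,
    cfg: QCConfig | None = None,
    k50: GenotypeMatrix | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full deterministic cascade: animals -> markers -> concordance ->
    parentage -> Mendelian repair. Returns the edited HD matrix and the
    replayable report."""
    cfg = cfg or QCConfig()
    cfg.validate()
    report = QCReport()
    g, r = filter_animals_by_call_rate(hd, cfg)
    report.extend(r)
    g, r = filter_markers(g, cfg)
    report.extend(r)
    if k50 is not None:
        r = cross_chip_concordance(g, k50, cfg)
        report.extend(r)
        drop = {m for m, _ in r.removed_markers}
        if drop:
            g = g.subset(markers=[m for m in g.marker_ids if m not in drop])
    if _genotyped_pairs(g, ped):
        r = parentage_test(g, ped, cfg)
        report.extend(r)
        drop_a = {a for a, _ in r.removed_animals}
        if drop_a:
            g = g.subset(animals=[a for a in g.animal_ids if a not in drop_a])
        g, r = mendelian_repair(g, ped, cfg)
        report.extend(r)
    return g, report
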
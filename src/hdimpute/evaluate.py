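"""Imputation-accuracy evaluation.

The validation design mirrors a two-panel accuracy study: within each
breed the youngest 20% of genotyped animals form the validation set, their
HD-only markers are masked to mimic medium-density genotypes, and the
masked genotypes are re-imputed from the older (reference) animals. The
headline statistic is the allelic imputation error rate — falsely imputed
alleles over total imputed alleles, where a het/hom disagreement counts
one allele and opposite homozygotes count two. Per-SNP error rates across
several breeds feed a mean + 3 SD outlier rule that recovers mismapped
markers, and a MAF profile separates low-error SNPs (error independent of
MAF) from high-error SNPs (error rising with MAF, the signature of a SNP
imputed at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, MarkerMap, Pedigree
from .impute import HaplotypeCopyingImputer, ImputationConfig, ImputedGenotypes
from .simulate import SimulatedDataset

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    validation_fraction: float = 0.20
    breed: str = ""

    def validate(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


def split_by_age(ped: Pedigree, genotyped_ids, spec: SplitSpec | None = None):
    """Oldest animals train, youngest ``floor(fraction * N)`` validate.

    Age order is (birth_year, animal_id); larger is younger. Returns
    (training_ids, validation_ids), a disjoint exhaustive partition.
    """
    spec = spec or SplitSpec()
    spec.validate()
    ids = list(genotyped_ids)
    years = ped.birth_years()
    missing = [a for a in ids if a not in years]
    if missing:
        raise ValueError(f"animals without birth year in pedigree: {missing[:5]}")
    ordered = sorted(ids, key=lambda a: (years[a], a))
    n_valid = int(np.floor(spec.validation_fraction * len(ids)))
    training = ordered[: len(ids) - n_valid]
    validation = ordered[len(ids) - n_valid :]
    return training, validation


def mask_hd_only(g: GenotypeMatrix, marker_map: MarkerMap) -> GenotypeMatrix:
    """Set every HD-only marker to MISSING, mimicking 50K genotypes."""
    out = g.copy()
    hd_only = set(marker_map.hd_only_ids())
    cols = [j for j, m in enumerate(out.marker_ids) if m in hd_only]
    out.calls[:, cols] = MISSING
    return out


@dataclass
class ErrorReport:
    overall_error: float
    per_animal_error: dict
    per_snp_error: dict
    n_alleles_compared: int
    per_snp_n: dict = field(default_factory=dict)


def allelic_error_rate(
    imputed: ImputedGenotypes | GenotypeMatrix,
    truth: GenotypeMatrix,
    masked_markers,
) -> ErrorReport:
    """Allelic error rate over masked, truth-non-missing entries.

    The allele distance between dosage codes is ``|imputed - truth|``
    (0, 1 or 2 wrong alleles out of the 2 imputed); totals are aggregated
    overall, per animal and per SNP. ``overall_error`` is the ratio of
    total wrong alleles to total imputed alleles, not a mean of rates.
    """
    calls = imputed.hard_calls if isinstance(imputed, ImputedGenotypes) else imputed
    masked = list(masked_markers)
    if not masked:
        raise ValueError("no masked markers to evaluate")
    sub_i = calls.subset(markers=masked)
    sub_t = truth.subset(animals=list(calls.animal_ids), markers=masked)
    comparable = (sub_t.calls != MISSING) & (sub_i.calls != MISSING)
    if not comparable.any():
        raise ValueError("no comparable entries (all truth or imputed calls missing)")
    diff = np.abs(sub_i.calls.astype(np.int16) - sub_t.calls.astype(np.int16))
    diff = np.where(comparable, diff, 0)
    n_entries = comparable.sum()
    wrong = diff.sum()
    per_animal = {}
    a_n = comparable.sum(axis=1)
    a_w = diff.sum(axis=1)
    for i, a in enumerate(sub_i.animal_ids):
        if a_n[i] > 0:
            per_animal[str(a)] = a_w[i] / (2.0 * a_n[i])
    per_snp = {}
    per_snp_n = {}
    m_n = comparable.sum(axis=0)
    m_w = diff.sum(axis=0)
    for j, mid in enumerate(sub_i.marker_ids):
        if m_n[j] > 0:
            per_snp[str(mid)] = m_w[j] / (2.0 * m_n[j])
            per_snp_n[str(mid)] = int(2 * m_n[j])
    return ErrorReport(
        overall_error=float(wrong / (2.0 * n_entries)),
        per_animal_error=per_animal,
        per_snp_error=per_snp,
        n_alleles_compared=int(2 * n_entries),
        per_snp_n=per_snp_n,
    )


def detect_high_error_snps(
    reports: dict[str, ErrorReport],
    min_breeds: int,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """SNPs whose error exceeds mean + 3 SD in at least ``min_breeds`` breeds.

    The per-breed threshold is computed over all of that breed's evaluated
    SNPs (zeros included) with a strict comparison. Columns follow the
    chromosome / SNP name / number of breeds / mean error layout.
    """
    if len(reports) < min_breeds:
        raise ValueError(f"need at least {min_breeds} breed reports, got {len(reports)}")
    flags: dict[str, list[str]] = {}
    errors: dict[str, list[float]] = {}
    for breed, rep in reports.items():
        vals = np.array(list(rep.per_snp_error.values()))
        if len(vals) < 2:
            raise ValueError(f"breed {breed}: fewer than 2 evaluated SNPs (SD undefined)")
        thr = vals.mean() + 3.0 * vals.std(ddof=0)
        for mid, err in rep.per_snp_error.items():
            errors.setdefault(mid, []).append(err)
            if err > thr:
                flags.setdefault(mid, []).append(breed)
    chrom_of = {}
    if marker_map is not None:
        chrom_of = dict(zip(marker_map.marker_ids, marker_map.chromosomes))
    rows = []
    for mid, breeds in flags.items():
        if len(breeds) >= min_breeds:
            rows.append(
                {
                    "chromosome": chrom_of.get(mid, 0),
                    "snp_name": mid,
                    "n_breeds": len(breeds),
                    "mean_error": float(np.mean(errors[mid])),
                    "breeds_flagged": ",".join(sorted(breeds)),
                }
            )
    out = pd.DataFrame(rows, columns=["chromosome", "snp_name", "n_breeds", "mean_error", "breeds_flagged"])
    return out.sort_values(["chromosome", "snp_name"]).reset_index(drop=True)


def maf_error_profile(
    report: ErrorReport,
    truth: GenotypeMatrix,
    split_at: float = 0.1,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean per-SNP error by MAF decile, split into low/high error groups.

    MAF is computed from the truth genotypes of the evaluated animals.
    Returns columns (maf_bin, group, mean_error, n_snps); an empty group is
    omitted with a warning.
    """
    snps = [m for m in report.per_snp_error]
    maf_all = truth.minor_allele_frequency()
    maf_of = dict(zip(truth.marker_ids, maf_all))
    maf = np.array([maf_of[m] for m in snps])
    err = np.array([report.per_snp_error[m] for m in snps])
    # equal-frequency MAF bins over the evaluated SNPs
    quantiles = np.quantile(maf, np.linspace(0, 1, n_bins + 1))
    quantiles[-1] += 1e-12
    bins = np.clip(np.searchsorted(quantiles, maf, side="right") - 1, 0, n_bins - 1)
    rows = []
    for group, mask in (("low", err < split_at), ("high", err >= split_at)):
        if not mask.any():
            logger.warning("maf_error_profile: group %r is empty, omitted", group)
            continue
        for b in range(n_bins):
            sel = mask & (bins == b)
            if sel.any():
                rows.append(
                    {
                        "maf_bin": b,
                        "maf_mid": float((quantiles[b] + quantiles[b + 1]) / 2),
                        "group": group,
                        "mean_error": float(err[sel].mean()),
                        "n_snps": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows, columns=["maf_bin", "maf_mid", "group", "mean_error", "n_snps"])


def evaluate_breed(
    data: SimulatedDataset,
    cfg: ImputationConfig | None = None,
    spec: SplitSpec | None = None,
) -> tuple[ErrorReport, dict]:
    """Run the full within-breed validation design on one dataset.

    Splits by age, phases the training panel, masks HD-only markers in the
    validation animals, imputes, and scores against the simulated truth.
    Returns the error report plus the split/masking bookkeeping.
    """
    cfg = cfg or ImputationConfig()
    train_ids, valid_ids = split_by_age(data.pedigree, list(data.genotypes.animal_ids), spec)
    train_g = data.genotypes.subset(animals=train_ids)
    valid_g = data.genotypes.subset(animals=valid_ids)
    masked_valid = mask_hd_only(valid_g, data.marker_map)
    imp = HaplotypeCopyingImputer(**cfg.__dict__)
    imp.fit(train_g, data.marker_map)
    imputed = imp.predict(masked_valid)
    truth = data.truth_haplotypes.to_genotypes()
    masked_markers = list(data.marker_map.hd_only_ids())
    report = allelic_error_rate(imputed, truth, masked_markers)
    return report, {
        "training_ids": train_ids,
        "validation_ids": valid_ids,
        "masked_markers": masked_markers,
        "imputed": imputed,
    }


def multibreed_evaluate(
    datasets: dict[str, SimulatedDataset],
    groups: list[list[str]],
    cfg: ImputationConfig | None = None,
    spec: SplitSpec | None = None,
) -> pd.DataFrame:
    """Single- vs pooled-reference imputation per breed.

    Each group's training panels are pooled (deduplicated by animal id) and
    used to impute every member breed's validation set on the identical
    split used for the single-breed baseline. Per-animal error rates are
    averaged within breed. Returns rows (breed, single_error, multi_error).
    """
    cfg = cfg or ImputationConfig()
    seen: set[str] = set()
    deduped_groups = []
    for group in groups:
        unique = list(dict.fromkeys(group))  # within-group repeats collapse
        for breed in unique:
            if breed in seen:
                raise ValueError(f"breed {breed} appears in more than one group")
            seen.add(breed)
            if breed not in datasets:
                raise KeyError(f"no dataset for breed {breed}")
        deduped_groups.append(unique)
    rows = []
    for group in deduped_groups:
        splits = {}
        single_reports = {}
        panels = {}
        for breed in group:
            report, info = evaluate_breed(datasets[breed], cfg, spec)
            splits[breed] = info
            single_reports[breed] = report
        # pooled reference: phase each breed's training panel, concatenate
        for breed in group:
            data = datasets[breed]
            train_g = data.genotypes.subset(animals=splits[breed]["training_ids"])
            imp = HaplotypeCopyingImputer(**cfg.__dict__)
            imp.fit(train_g, data.marker_map)
            panels[breed] = imp.reference_
        for breed in group:
            data = datasets[breed]
            ref_alleles = []
            ref_animals = []
            seen_animals = set()
            for other in group:
                panel = panels[other].subset(markers=data.marker_map.marker_ids)
                for i, a in enumerate(panel.animal_ids):
                    if a in seen_animals:
                        continue
                    seen_animals.add(a)
                    ref_animals.append(a)
                    ref_alleles.append(panel.alleles[2 * i : 2 * i + 2])
            from .model import HaplotypePanel

            pooled = HaplotypePanel(
                np.asarray(ref_animals, dtype=object),
                data.marker_map.marker_ids,
                np.vstack(ref_alleles),
            )
            imp = HaplotypeCopyingImputer(**cfg.__dict__)
            imp.fit(pooled, data.marker_map)
            valid_g = data.genotypes.subset(animals=splits[breed]["validation_ids"])
            imputed = imp.predict(mask_hd_only(valid_g, data.marker_map))
            truth = data.truth_haplotypes.to_genotypes()
            multi_report = allelic_error_rate(imputed, truth, splits[breed]["masked_markers"])
            single_mean = float(np.mean(list(single_reports[breed].per_animal_error.values())))
            multi_mean = float(np.mean(list(multi_report.per_animal_error.values())))
            rows.append({"breed": breed, "single_error": single_mean, "multi_error": multi_mean})
    return pd.DataFrame(rows, columns=["breed", "single_error", "multi_error"])
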
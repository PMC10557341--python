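"""Genetic risk score construction and instrument-strength diagnostics.

Harmonizes external GWAS weights to the alleles a genotype matrix
counts, builds weighted (sum of beta x dosage) and unweighted (count of
trait-increasing alleles) scores, reports instrument strength as the
R-squared and F-statistic of the exposure-on-score regression, and
splits scores at the sample median for factorial designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import GenotypeMatrix, VariantWeight

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass
class HarmonizationReport:
    """What happened to each variant during weight/genotype alignment."""

    n_input: int
    matched: list[str]
    flipped: list[str]       # beta sign flipped (effect allele was the
                             # non-counted allele)
    dropped_missing: list[str]
    dropped_mismatch: list[str]
    dropped_palindromic: list[str]
    palindromic: list[str]

    @property
    def n_used(self) -> int:
        return len(self.matched)


def harmonize(
    weights: Sequence[VariantWeight],
    genotype_meta: pd.DataFrame,
    *,
    strict_palindromic: bool = False,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[VariantWeight], HarmonizationReport]:
    """Align external weights to the allele each genotype column counts.

    ``genotype_meta`` has columns variant_id, counted_allele,
    other_allele.  Convention: the dosage is left untouched and the
    *beta is negated* (with eaf reflected) when the file's effect allele
    is the genotype's other allele — algebraically identical to counting
    2-dosage, up to an intercept that no downstream regression sees.

    Unmatched IDs and allele pairs that are neither a match nor a swap
    are dropped and reported, never silently.  Palindromic (A/T, C/G)
    variants are flagged; with ``strict_palindromic`` they are dropped
    when their EAF is inside the ambiguity window.
    """
    ids = list(genotype_meta["variant_id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant IDs in genotype metadata")
    wids = [w.variant_id for w in weights]
    if len(set(wids)) != len(wids):
        raise ValueError("duplicate variant IDs in weights")
    meta = {
        str(r.variant_id): (str(r.counted_allele), str(r.other_allele))
        for r in genotype_meta.itertuples()
    }

    aligned: list[VariantWeight] = []
    report = HarmonizationReport(
        n_input=len(weights),
        matched=[], flipped=[], dropped_missing=[],
        dropped_mismatch=[], dropped_palindromic=[], palindromic=[],
    )
    lo, hi = palindromic_eaf_window
    for w in weights:
        if w.variant_id not in meta:
            report.dropped_missing.append(w.variant_id)
            continue
        counted, other = meta[w.variant_id]
        if _is_palindromic(w.effect_allele, w.other_allele):
            report.palindromic.append(w.variant_id)
            if strict_palindromic and lo <= w.eaf <= hi:
                report.dropped_palindromic.append(w.variant_id)
                warnings.warn(
                    f"{w.variant_id}: palindromic with ambiguous EAF "
                    f"{w.eaf:.2f}, dropped in strict mode"
                )
                continue
        if (w.effect_allele, w.other_allele) == (counted, other):
            aligned.append(w)
        elif (w.effect_allele, w.other_allele) == (other, counted):
            aligned.append(
                replace(w, effect_allele=counted, other_allele=other,
                        beta=-w.beta, eaf=1.0 - w.eaf)
            )
            report.flipped.append(w.variant_id)
        else:
            report.dropped_mismatch.append(w.variant_id)
            warnings.warn(
                f"{w.variant_id}: alleles {w.effect_allele}/{w.other_allele}"
                f" incompatible with genotype {counted}/{other}, dropped"
            )
            continue
        report.matched.append(w.variant_id)
    return aligned, report


def genotype_meta_from_variants(
    variants: Sequence[VariantWeight],
) -> pd.DataFrame:
    """Metadata for a genotype matrix that counts each effect allele."""
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "counted_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
        }
    )


@dataclass
class GRSVector:
    score: np.ndarray
    weighted: bool
    n_variants_used: int
    trait: str = ""

    def series(self, sample_ids: Sequence[str]) -> pd.Series:
        return pd.Series(self.score, index=list(sample_ids), name="score")


def compute_grs(
    genotypes: GenotypeMatrix,
    aligned: Sequence[VariantWeight],
    mode: Literal["weighted", "unweighted"] = "weighted",
    trait: str = "",
) -> GRSVector:
    """Weighted (sum beta_j * dosage_j) or unweighted GRS.

    The unweighted score counts trait-increasing alleles: where the
    aligned beta is negative the dosage is reflected (2 - dosage) so
    every counted allele raises the trait and both score flavours point
    the same way.
    """
    if len(aligned) == 0:
        raise ValueError("no variants to score")
    col = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    try:
        idx = [col[w.variant_id] for w in aligned]
    except KeyError as exc:
        raise ValueError(f"variant {exc} absent from genotype matrix")
    dose = genotypes.dosage[:, idx]
    betas = np.array([w.beta for w in aligned])
    if mode == "weighted":
        score = dose @ betas
    elif mode == "unweighted":
        increasing = np.where(betas[None, :] >= 0, dose, 2.0 - dose)
        score = increasing.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GRSVector(
        score=score,
        weighted=(mode == "weighted"),
        n_variants_used=len(aligned),
        trait=trait,
    )


@dataclass(frozen=True)
class InstrumentStrength:
    r2: float
    f_stat: float
    n: int
    r2_mcfadden: float | None = None


def instrument_strength(
    exposure: np.ndarray,
    grs: np.ndarray,
    *,
    mcfadden: bool = False,
) -> InstrumentStrength:
    """R-squared and F from regressing the exposure on the score.

    A single-regressor least-squares fit (a linear-probability model
    when the exposure is binary), with F = R2 (n-2) / (1 - R2).  For a
    binary exposure ``mcfadden`` adds the logistic pseudo-R2.
    """
    x = np.asarray(exposure, dtype=float)
    g = np.asarray(grs, dtype=float)
    if x.size != g.size:
        raise ValueError("exposure and grs lengths differ")
    n = x.size
    if n <= 2:
        raise ValueError("need n > 2")
    if x.std() == 0 or g.std() == 0:
        raise ValueError("constant exposure or GRS")
    r = np.corrcoef(x, g)[0, 1]
    r2 = float(r * r)
    f = r2 * (n - 2) / (1.0 - r2) if r2 < 1 else np.inf
    r2_mcf = None
    if mcfadden:
        uniq = np.unique(x)
        if not np.array_equal(uniq, uniq.astype(int)) or len(uniq) > 2:
            raise ValueError("mcfadden R2 requires a binary exposure")
        fit = sm.Logit(x, sm.add_constant(g)).fit(disp=0)
        r2_mcf = float(1.0 - fit.llf / fit.llnull)
    return InstrumentStrength(r2=r2, f_stat=float(f), n=n, r2_mcfadden=r2_mcf)


def dichotomize_at_median(grs: np.ndarray) -> np.ndarray:
    """Median split: scores <= median are "low", above are "high"."""
    g = np.asarray(grs, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 samples to split")
    med = np.median(g)
    if np.all(g == g[0]):
        warnings.warn("all scores equal; everyone assigned to 'low'")
    return np.where(g <= med, "low", "high")
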
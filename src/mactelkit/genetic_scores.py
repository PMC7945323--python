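"""Polygenic allele scores from external instrument weights.

Builds weighted allele scores (metabolite PRS / trait PRS) by applying
externally estimated per-allele weights to cohort dosages: the score for
subject i is ``sum_j w_j * g_ij`` over the trait's instrument SNPs.
Because the weights come from an external GWAS, each instrument must
first be harmonised to the cohort's counted allele: weights are
sign-flipped when the cohort counts the instrument's other allele
(directly or on the opposite strand), and strand-ambiguous palindromic
SNPs (A/T, C/G) are dropped since their orientation cannot be resolved
without frequency information.

Scores are standardized within the analysis cohort (cases and controls
pooled), so downstream odds ratios are per one standard deviation of the
score distribution.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import CohortGenotypes, InstrumentSet, ScoreMatrix
from .errors import DataError, DegenerateScoreError, EmptyInstrumentError

__all__ = [
    "harmonise_instruments", "compute_allele_score", "build_scores",
    "standardize_scores", "unstandardize_scores",
    "read_instrument_tsv", "write_instrument_tsv",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonise_instruments(instruments: InstrumentSet,
                          genotypes: CohortGenotypes) -> InstrumentSet:
    """Align instrument weights to the cohort's counted alleles.

    For each instrument SNP present in the genotype panel:

    * counted allele == instrument effect allele (same or complement
      strand): weight kept;
    * counted allele == instrument other allele (same or complement
      strand): weight sign-flipped;
    * palindromic (A/T or C/G) instruments: dropped and counted, the
      strand being unresolvable;
    * allele pairs that match neither orientation: dropped and counted.

    Raises :class:`EmptyInstrumentError` when nothing survives.
    """
    if len(instruments) == 0:
        raise EmptyInstrumentError(
            f"{instruments.trait_name}: empty instrument table")
    panel = {sid: j for j, sid in enumerate(genotypes.snp_ids)}
    rows = []
    excluded = []
    n_palindromic = 0
    for rec in instruments.table.itertuples(index=False):
        j = panel.get(rec.snp_id)
        if j is None:
            excluded.append((rec.snp_id, "absent from panel"))
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if _is_palindromic(ea, oa):
            n_palindromic += 1
            excluded.append((rec.snp_id, "palindromic"))
            continue
        counted = genotypes.effect_alleles[j]
        other = genotypes.other_alleles[j]
        cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
        if (counted, other) in ((ea, oa), (cea, coa)):
            flip = 1.0
        elif (counted, other) in ((oa, ea), (coa, cea)):
            flip = -1.0
        else:
            excluded.append((rec.snp_id, "allele mismatch"))
            continue
        rows.append({"snp_id": rec.snp_id,
                     "effect_allele": counted,
                     "other_allele": other,
                     "weight": flip * rec.weight,
                     "source_pvalue": rec.source_pvalue})
    if not rows:
        raise EmptyInstrumentError(
            f"{instruments.trait_name}: no instrument SNP overlaps the "
            "genotype panel after harmonisation")
    for sid, why in excluded:
        log.info("%s: dropped instrument %s (%s)",
                 instruments.trait_name, sid, why)
    return InstrumentSet(
        trait_name=instruments.trait_name,
        table=pd.DataFrame(rows),
        genome_wide=instruments.genome_wide,
        n_excluded_palindromic=n_palindromic,
        excluded_snps=excluded,
    )


def compute_allele_score(genotypes: CohortGenotypes,
                         instruments: InstrumentSet) -> np.ndarray:
    """Raw weighted allele score per subject.

    Missing dosages are mean-imputed per SNP before summation, the
    conventional allele-score choice, so the score is defined for every
    subject.  A SNP with no observed dosage at all is unrecoverable and
    raises :class:`DataError` naming it.
    """
    idx = [genotypes.snp_index(s) for s in instruments.snp_ids]
    g = genotypes.dosages[:, idx].copy()
    for col, sid in enumerate(instruments.snp_ids):
        miss = np.isnan(g[:, col])
        if miss.all():
            raise DataError(f"SNP {sid} has no observed dosages")
        if miss.any():
            g[miss, col] = g[~miss, col].mean()
    return g @ instruments.weights


def build_scores(genotypes: CohortGenotypes,
                 instrument_map: dict,
                 standardize: bool = True) -> ScoreMatrix:
    """Harmonise and score every trait, returning a ScoreMatrix."""
    traits, cols = [], []
    for name, inst in instrument_map.items():
        harm = harmonise_instruments(inst, genotypes)
        cols.append(compute_allele_score(genotypes, harm))
        traits.append(name)
    sm = ScoreMatrix(subject_ids=genotypes.subject_ids,
                     trait_names=traits,
                     scores=np.column_stack(cols))
    return standardize_scores(sm) if standardize else sm


def standardize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Centre and scale each score column by its sample SD.

    Idempotent; stores the means/SDs of the *original raw* scores so the
    transform inverts exactly even after repeated application.
    """
    if scores.standardized:
        return scores
    means = scores.scores.mean(axis=0)
    sds = scores.scores.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [scores.trait_names[j] for j in zero]
        raise DegenerateScoreError(
            f"zero-variance score column(s): {names}")
    return ScoreMatrix(
        subject_ids=scores.subject_ids,
        trait_names=list(scores.trait_names),
        scores=(scores.scores - means) / sds,
        standardized=True,
        means=means,
        sds=sds,
    )


def unstandardize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Exact inverse of :func:`standardize_scores`."""
    if not scores.standardized:
        return scores
    return ScoreMatrix(
        subject_ids=scores.subject_ids,
        trait_names=list(scores.trait_names),
        scores=scores.scores * scores.sds + scores.means,
        standardized=False,
    )


# ---------------------------------------------------------------------------
# instrument-table I/O (TSV, fixed header: trait, snp_id, effect_allele,
# other_allele, weight, pvalue)

def write_instrument_tsv(instrument_map: dict, path) -> None:
    frames = []
    for name, inst in instrument_map.items():
        df = inst.table.rename(columns={"source_pvalue": "pvalue"})
        df.insert(0, "trait", name)
        frames.append(df[["trait", "snp_id", "effect_allele",
                          "other_allele", "weight", "pvalue"]])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_instrument_tsv(path, genome_wide: bool = False) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for name, grp in df.groupby("trait", sort=False):
        out[name] = InstrumentSet(
            trait_name=name,
            table=grp.rename(columns={"pvalue": "source_pvalue"})
                     .drop(columns=["trait"]).reset_index(drop=True),
            genome_wide=genome_wide,
        )
    return out
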
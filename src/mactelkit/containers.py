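"""Core in-memory containers shared across the analysis stages.

The cohort is held as a subjects x SNPs dosage matrix plus per-subject
covariates (:class:`CohortGenotypes`); externally derived instrument
weights live in :class:`InstrumentSet`; per-subject polygenic scores in
:class:`ScoreMatrix`.  Longitudinal retinal phenotypes travel as a plain
long-format :class:`pandas.DataFrame` with a fixed column set, validated
by :func:`validate_retinal_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

RETINAL_COLUMNS = ["patient_id", "eye", "visit_index", "visit_time",
                   "phenotype", "subfield", "value"]

#: ETDRS macular grid: subfield number -> anatomical name.  Subfield 5
#: (temporal inner) is the disease-onset "MacTel area"; the other inner
#: subfields (2-4) are the progression areas.
ETDRS_SUBFIELDS = {
    1: "foveal area",
    2: "superior inner area",
    3: "nasal inner area",
    4: "inferior inner area",
    5: "temporal inner area",
    6: "superior outer area",
    7: "nasal outer area",
    8: "inferior outer area",
    9: "temporal outer area",
}
MACTEL_AREA_SUBFIELD = 5
PROGRESSION_AREA_SUBFIELDS = (2, 3, 4)


@dataclass
class CohortGenotypes:
    """Subjects x SNPs dosage matrix with case/control status and covariates.

    Dosages count copies of the per-SNP ``effect_alleles`` entry and lie
    in [0, 2]; missing genotypes are ``NaN``, never a sentinel value.
    ``status`` is 1 for cases, 0 for controls, or None before the
    disease stage has run.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    dosages: np.ndarray
    sex: np.ndarray
    pc1: np.ndarray
    status: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    mafs: np.ndarray | None = None

    def __post_init__(self):
        n, s = self.dosages.shape
        if len(self.subject_ids) != n:
            raise DataError("subject_ids length does not match dosage rows")
        for name in ("sex", "pc1"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length does not match subject count")
        if self.status is not None and len(self.status) != n:
            raise DataError("status length does not match subject count")
        if len(self.snp_ids) != s:
            raise DataError("snp_ids length does not match dosage columns")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or \
               np.nanmax(self.dosages, initial=0) > 2:
                raise DataError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])

    def subset_subjects(self, idx: np.ndarray) -> "CohortGenotypes":
        return replace(
            self,
            subject_ids=self.subject_ids[idx],
            dosages=self.dosages[idx],
            sex=self.sex[idx],
            pc1=self.pc1[idx],
            status=None if self.status is None else self.status[idx],
        )

    def subset_snps(self, idx: np.ndarray) -> "CohortGenotypes":
        return replace(
            self,
            snp_ids=self.snp_ids[idx],
            effect_alleles=self.effect_alleles[idx],
            other_alleles=self.other_alleles[idx],
            dosages=self.dosages[:, idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            mafs=None if self.mafs is None else self.mafs[idx],
        )

    def covariate_frame(self) -> pd.DataFrame:
        d = {"subject_id": self.subject_ids, "sex": self.sex, "pc1": self.pc1}
        if self.status is not None:
            d["status"] = self.status
        return pd.DataFrame(d)

    def dosage_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class InstrumentSet:
    """Per-trait instrument SNPs with effect alleles and per-allele weights.

    Weights are the externally estimated per-allele effects on the trait
    (in trait SDs or native units); ``source_pvalue`` is the discovery
    association p-value.  When ``genome_wide`` is set, every source
    p-value must clear the genome-wide threshold of 5e-8.
    """

    trait_name: str
    table: pd.DataFrame  # columns: snp_id, effect_allele, other_allele, weight, source_pvalue
    genome_wide: bool = False
    n_excluded_palindromic: int = 0
    excluded_snps: list = field(default_factory=list)

    REQUIRED = ["snp_id", "effect_allele", "other_allele", "weight"]
    GWS_THRESHOLD = 5e-8

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"instrument table missing columns: {missing}")
        if "source_pvalue" not in self.table.columns:
            self.table = self.table.assign(source_pvalue=np.nan)
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise DataError(f"duplicate instrument SNPs: {sorted(set(dups))}")
        w = self.table["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)) or np.any(w == 0):
            raise DataError("instrument weights must be finite and nonzero")
        if self.genome_wide:
            p = self.table["source_pvalue"].to_numpy(float)
            if np.any(p > self.GWS_THRESHOLD):
                raise DataError(
                    f"{self.trait_name}: genome-wide instrument set contains "
                    f"source p-values above {self.GWS_THRESHOLD:g}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)


@dataclass
class ScoreMatrix:
    """Subjects x traits allele scores, optionally standardized.

    Standardization constants (per-trait mean and sample SD of the raw
    scores) are retained so the affine transform is exactly invertible.
    """

    subject_ids: np.ndarray
    trait_names: list
    scores: np.ndarray
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def column(self, trait: str) -> np.ndarray:
        try:
            j = self.trait_names.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in score matrix") from None
        return self.scores[:, j]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.trait_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def validate_retinal_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format retinal phenotype table schema and keys."""
    missing = [c for c in RETINAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"retinal table missing columns: {missing}")
    if len(table) == 0:
        raise DataError("retinal phenotype table is empty")
    bad_eye = set(table["eye"].unique()) - {"OD", "OS"}
    if bad_eye:
        raise DataError(f"eye must be OD or OS, got {sorted(bad_eye)}")
    sub = table["subfield"].to_numpy()
    if sub.min() < 1 or sub.max() > 9:
        raise DataError("subfield must lie in 1..9 (ETDRS grid)")
    key = ["patient_id", "eye", "visit_index", "phenotype", "subfield"]
    if table.duplicated(subset=key).any():
        raise DataError("(patient, eye, visit, phenotype, subfield) "
                        "key is not unique")
    return table
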
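"""Shared domain types and tabular readers/writers.

Every analysis stage consumes one of a small set of containers defined here:
per-variant allele counts across populations (:class:`VariantRecord`),
case-control dosage matrices (:class:`GenotypeMatrix`), per-study association
summaries (:class:`StudySummary`) and per-variant effect/frequency tables
(:class:`EffectTable`).

Coordinates are 1-based point positions (GRCh37 naming convention); indels
are represented exactly as given — no normalization is performed here, it is
assumed done upstream.

The TSV dialect used throughout: tab-separated, header line prefixed with
``#``, UTF-8, ``.`` for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "PopulationCounts",
    "VariantRecord",
    "GenotypeMatrix",
    "StudySummary",
    "EffectTable",
    "SchemaError",
    "ValidationError",
    "read_variant_counts",
    "read_genotypes",
    "write_results",
    "read_table",
]

MISSING = "."


class SchemaError(ValueError):
    """A required column or field is absent from an input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. AC > AN)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant, keyed chrom:pos:ref:alt (1-based, GRCh37 style)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"alleles must be non-empty in {self!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt in {self.chrom}:{self.pos}:{self.ref}:{self.alt}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse the canonical "chrom:pos:ref:alt" rendering."""
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise ValidationError(f"cannot parse variant key {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


@dataclass(frozen=True)
class PopulationCounts:
    """ALT allele count and total allele number (AN) for one population."""

    population: str
    alt_count: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValidationError(
                f"{self.population}: total_alleles must be positive, got {self.total_alleles}"
            )
        if not 0 <= self.alt_count <= self.total_alleles:
            raise ValidationError(
                f"{self.population}: need 0 <= AC <= AN, got AC={self.alt_count}, AN={self.total_alleles}"
            )

    @property
    def ref_count(self) -> int:
        return self.total_alleles - self.alt_count

    @property
    def frequency(self) -> float:
        return self.alt_count / self.total_alleles


ANNOTATION_CLASSES = ("PTV", "PRA", "SYN", "OTHER")


@dataclass
class VariantRecord:
    """One variant's counts in the study population and each reference population."""

    key: VariantKey
    annotation: str
    counts: dict[str, PopulationCounts]
    coverage_ok: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.annotation not in ANNOTATION_CLASSES:
            raise ValidationError(
                f"{self.key}: annotation {self.annotation!r} not one of {ANNOTATION_CLASSES}"
            )
        if len(self.counts) < 2:
            raise ValidationError(
                f"{self.key}: need at least a study and one reference population"
            )

    def frequency(self, population: str) -> float:
        return self.counts[population].frequency


@dataclass(frozen=True)
class StudySummary:
    """Per-study log-odds-ratio estimate and its standard error."""

    study: str
    beta_hat: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta_hat):
            raise ValidationError(f"{self.study}: beta_hat must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"{self.study}: se must be positive and finite")


class GenotypeMatrix:
    """Samples x variants dosage matrix with phenotype and covariates.

    Dosages are in [0, 2] (hard calls 0/1/2, or imputed expected values);
    missing entries are flagged in ``missing_mask`` and stored as NaN in
    ``dosages`` — they are never silently imputed here. How missingness is
    handled is the caller's choice: the PRS module imputes ``2f``, the
    association module drops to per-variant complete cases.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_keys: Sequence[VariantKey],
        dosages: np.ndarray,
        phenotype: np.ndarray,
        covariates: np.ndarray | None = None,
        missing_mask: np.ndarray | None = None,
    ):
        dosages = np.asarray(dosages, dtype=float)
        phenotype = np.asarray(phenotype)
        n, m = dosages.shape
        if len(sample_ids) != n or len(variant_keys) != m:
            raise ValidationError("dosage matrix shape does not match ids")
        if missing_mask is None:
            missing_mask = np.isnan(dosages)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        observed = dosages[~missing_mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            bad = np.argwhere(~missing_mask & ((dosages < 0) | (dosages > 2)))[0]
            raise ValidationError(
                f"dosage out of [0, 2] for sample {sample_ids[bad[0]]}, "
                f"variant {variant_keys[bad[1]]}"
            )
        if not np.isin(phenotype, [0, 1]).all():
            raise ValidationError("phenotype must be binary 0/1")
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                raise ValidationError("covariate rows must match sample count")
        self.sample_ids = list(sample_ids)
        self.variant_keys = list(variant_keys)
        self.dosages = dosages
        self.phenotype = phenotype.astype(int)
        self.covariates = covariates
        self.missing_mask = missing_mask
        self._index = {k: i for i, k in enumerate(self.variant_keys)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column(self, key: VariantKey) -> np.ndarray:
        """Dosage vector for one variant (NaN where missing)."""
        j = self._index[key]
        col = self.dosages[:, j].copy()
        col[self.missing_mask[:, j]] = np.nan
        return col

    def call_rate(self, key: VariantKey) -> float:
        j = self._index[key]
        return 1.0 - self.missing_mask[:, j].mean()

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index


class EffectTable:
    """Per-variant effect sizes and per-population frequencies.

    The input for the PRS and liability stages. Effect alleles are always the
    alt allele of the :class:`VariantKey`. ``beta_het``/``beta_hom`` (genotype
    -specific log-ORs) must be supplied together or not at all.
    """

    def __init__(self, frame: pd.DataFrame):
        if "variant" not in frame.columns or "beta" not in frame.columns:
            raise SchemaError("effect table needs 'variant' and 'beta' columns")
        frame = frame.copy()
        frame["key"] = frame["variant"].map(
            lambda v: v if isinstance(v, VariantKey) else VariantKey.parse(str(v))
        )
        has_het = "beta_het" in frame.columns
        has_hom = "beta_hom" in frame.columns
        if has_het != has_hom:
            raise SchemaError("beta_het and beta_hom must both be present or both absent")
        self.nonadditive = has_het
        for col in frame.columns:
            if col.startswith("freq_"):
                bad = frame[(frame[col] < 0) | (frame[col] > 1)]
                if len(bad):
                    raise ValidationError(
                        f"{col}: frequency outside [0,1] for {bad['key'].iloc[0]}"
                    )
        self.frame = frame.set_index(frame["key"].map(str))

    @property
    def keys(self) -> list[VariantKey]:
        return list(self.frame["key"])

    @property
    def betas(self) -> np.ndarray:
        return self.frame["beta"].to_numpy(dtype=float)

    def frequencies(self, population: str) -> np.ndarray:
        col = f"freq_{population}"
        if col not in self.frame.columns:
            raise SchemaError(f"no frequency column for population {population!r}")
        vals = self.frame[col]
        if vals.isna().any():
            missing = self.frame.loc[vals.isna(), "key"].iloc[0]
            raise ValidationError(f"missing {population} frequency for {missing}")
        return vals.to_numpy(dtype=float)

    def het_hom_betas(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.nonadditive:
            raise SchemaError("effect table has no beta_het/beta_hom columns")
        het = self.frame["beta_het"].to_numpy(dtype=float)
        hom = self.frame["beta_hom"].to_numpy(dtype=float)
        if np.isnan(het).any() or np.isnan(hom).any():
            raise ValidationError("partial het/hom effect specification")
        return het, hom

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    """Read the package TSV dialect ('#'-prefixed header, '.' = missing)."""
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    if header.startswith("#"):
        names = header.lstrip("#").strip().split("\t")
        return pd.read_csv(path, sep="\t", skiprows=1, names=names, na_values=MISSING)
    return pd.read_csv(path, sep="\t", na_values=MISSING)


def write_results(records, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a homogeneous collection of result records (or a DataFrame) to TSV.

    Column order is deterministic; floats are serialized at fixed precision so
    that write -> read round-trips exactly at the serialized precision. An
    empty collection produces a header-only file (requires a DataFrame or
    dataclass list so the schema is known).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if not records:
            raise ValidationError("cannot infer schema from an empty non-DataFrame collection")
        rows = []
        schema = None
        for rec in records:
            if hasattr(rec, "to_row"):
                row = rec.to_row()
            elif hasattr(rec, "__dataclass_fields__"):
                row = {k: getattr(rec, k) for k in rec.__dataclass_fields__}
            elif isinstance(rec, Mapping):
                row = dict(rec)
            else:
                raise ValidationError(f"cannot serialize record of type {type(rec).__name__}")
            if schema is None:
                schema = tuple(row)
            elif tuple(row) != schema:
                raise ValidationError("records have mixed schemas")
            rows.append(row)
        frame = pd.DataFrame(rows)
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(
            fh, sep="\t", header=False, index=False,
            float_format=float_format, na_rep=MISSING,
        )


def _population_columns(columns: Iterable[str]) -> list[str]:
    pops = []
    for col in columns:
        if col.startswith("AC_"):
            pop = col[3:]
            if f"AN_{pop}" in columns:
                pops.append(pop)
    return pops


def read_variant_counts(
    path: str | Path,
    population_spec: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read per-variant, per-population allele counts from TSV or VCF.

    TSV columns: chrom, pos, ref, alt, annotation, then ``AC_<pop>`` /
    ``AN_<pop>`` pairs and optional ``coverage_ok_<pop>`` flags. A VCF path
    (suffix .vcf/.vcf.gz) is accepted with the same keys in INFO.

    ``population_spec`` optionally renames column suffixes to population
    labels, e.g. ``{"study": "AJ"}`` maps AC_study -> population "AJ".
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        frame = _vcf_to_frame(path)
    else:
        frame = read_table(path)
    required = ["chrom", "pos", "ref", "alt", "annotation"]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    pops = _population_columns(frame.columns)
    if not pops:
        raise SchemaError("no AC_<pop>/AN_<pop> column pairs found")
    rename = dict(population_spec or {})

    records: list[VariantRecord] = []
    errors: list[str] = []
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        rowd = row._asdict()
        try:
            key = VariantKey(
                chrom=str(rowd["chrom"]), pos=int(rowd["pos"]),
                ref=str(rowd["ref"]), alt=str(rowd["alt"]),
            )
            counts, cov = {}, {}
            for pop in pops:
                label = rename.get(pop, pop)
                counts[label] = PopulationCounts(
                    population=label,
                    alt_count=int(rowd[f"AC_{pop}"]),
                    total_alleles=int(rowd[f"AN_{pop}"]),
                )
                flag = rowd.get(f"coverage_ok_{pop}")
                if flag is not None and not (isinstance(flag, float) and math.isnan(flag)):
                    cov[label] = bool(int(flag)) if not isinstance(flag, bool) else flag
            records.append(
                VariantRecord(key=key, annotation=str(rowd["annotation"]),
                              counts=counts, coverage_ok=cov)
            )
        except (ValidationError, ValueError) as exc:
            ident = f"{rowd.get('chrom')}:{rowd.get('pos')}:{rowd.get('ref')}:{rowd.get('alt')}"
            errors.append(f"line {line_no} ({ident}): {exc}")
    if errors:
        raise ValidationError("malformed rows:\n" + "\n".join(errors))
    return records


def _vcf_to_frame(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    info_keys = [h["ID"] for h in vcf.header_iter()
                 if h.type == "INFO" and (h["ID"].startswith("AC_") or h["ID"].startswith("AN_")
                                          or h["ID"].startswith("coverage_ok_"))]
    rows = []
    for v in vcf:
        row = {
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "annotation": v.INFO.get("annotation", "OTHER"),
        }
        for k in info_keys:
            val = v.INFO.get(k)
            if val is not None:
                row[k] = val
        rows.append(row)
    return pd.DataFrame(rows)


def read_genotypes(
    path: str | Path,
    phenotype_path: str | Path | None = None,
    min_gq: float | None = None,
) -> GenotypeMatrix:
    """Read a samples-as-rows dosage TSV into a :class:`GenotypeMatrix`.

    Layout: first column ``sample``, then a ``phenotype`` column (or supply a
    sidecar TSV keyed by sample id via ``phenotype_path``), optional
    ``PC<k>`` covariate columns, then one column per variant named by its
    canonical key. '.' marks a missing call; missing calls are flagged in the
    mask, not imputed.
    """
    frame = read_table(path)
    if "sample" not in frame.columns:
        raise SchemaError("missing required column 'sample'")
    if phenotype_path is not None:
        side = read_table(phenotype_path).set_index("sample")
        frame = frame.join(side, on="sample")
    if "phenotype" not in frame.columns:
        raise SchemaError("missing required column 'phenotype'")
    pheno = frame["phenotype"].to_numpy()
    if not np.isin(pheno, [0, 1]).all():
        raise ValidationError("phenotype must be binary 0/1")
    covar_cols = [c for c in frame.columns if c.upper().startswith("PC")]
    variant_cols = [
        c for c in frame.columns
        if c not in {"sample", "phenotype"} and c not in covar_cols
    ]
    keys = [VariantKey.parse(c) for c in variant_cols]
    dosages = frame[variant_cols].to_numpy(dtype=float)
    covs = frame[covar_cols].to_numpy(dtype=float) if covar_cols else None
    return GenotypeMatrix(
        sample_ids=[str(s) for s in frame["sample"]],
        variant_keys=keys,
        dosages=dosages,
        phenotype=pheno.astype(int),
        covariates=covs,
    )


def read_effect_table(path: str | Path) -> EffectTable:
    """Read an effect-size table (variant, beta[, beta_het, beta_hom], freq_<pop>...)."""
    return EffectTable(read_table(path))


def read_study_summaries(path: str | Path) -> list[StudySummary]:
    frame = read_table(path)
    for col in ("study", "beta", "se"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    return [
        StudySummary(study=str(r.study), beta_hat=float(r.beta), se=float(r.se))
        for r in frame.itertuples(index=False)
    ]
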
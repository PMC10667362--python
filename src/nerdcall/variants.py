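"""Somatic variant ingestion and stringent filtering.

Reads MuTect2-dialect somatic VCFs (tumor/normal pair, TLOD/NLOD in
INFO, AD/DP/AF in FORMAT), applies the eight-predicate stringent filter
(caller PASS, TLOD >= 6, NLOD >= 3, normal depth >= 15, tumor depth >= 20,
tumor ALT reads >= 5, zero normal ALT reads, tumor allele fraction >= 0.05),
performs sample-level cohort selection (no WGA/FFPE/MSI samples, one
sample per patient, at least 50 passing variants), and classifies
deleterious mutations in the ERCC gene family.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DataError, VcfParseError

PATHOGENIC_LABELS = frozenset({"Pathogenic", "Likely Pathogenic"})
DEFAULT_ERCC_GENES = frozenset({"ERCC2", "ERCC3", "ERCC6"})


@dataclass
class VariantRecord:
    """One somatic call (one ALT allele) with caller statistics.

    ``pos`` is the 1-based VCF coordinate; ``filter_status`` the set of
    FILTER entries (``{"PASS"}`` for passing records).  Caller statistics
    missing from the VCF surface as ``None``, never as zeros.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: frozenset[str] = frozenset({"PASS"})
    tlod: float | None = None
    nlod: float | None = None
    tumor_depth: int | None = None
    normal_depth: int | None = None
    tumor_alt_count: int | None = None
    normal_alt_count: int | None = None
    tumor_af: float | None = None
    gene: str | None = None
    consequence: str | None = None
    pathogenicity_label: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be nonempty")
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")
        if not isinstance(self.filter_status, frozenset):
            self.filter_status = frozenset(self.filter_status)
        for alt_c, depth_c in (
            (self.tumor_alt_count, self.tumor_depth),
            (self.normal_alt_count, self.normal_depth),
        ):
            if alt_c is not None and depth_c is not None and alt_c > depth_c:
                raise ValueError("ALT read count exceeds depth")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleMetadata:
    """Cohort bookkeeping for one sequenced sample.

    The WGA/FFPE/MSI flags are consumed as given (MSI comes from an
    external MANTIS run); ``preference_rank`` orders a patient's samples
    for the one-sample-per-patient rule (lower wins, ties broken by
    lexicographic sample id).
    """

    sample_id: str
    patient_id: str
    is_wga: bool = False
    is_ffpe: bool = False
    is_msi: bool = False
    preference_rank: int = 1


@dataclass(frozen=True)
class FilterThresholds:
    """The stringent somatic filter, with its published defaults."""

    min_tlod: float = 6.0
    min_nlod: float = 3.0
    min_normal_depth: int = 15
    min_tumor_depth: int = 20
    min_tumor_alt: int = 5
    max_normal_alt: int = 0
    min_tumor_af: float = 0.05
    min_variants_per_sample: int = 50


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the eight-predicate filter for one record.

    ``reason`` is ``None`` for passing records, a predicate name for
    ordinary failures, or ``"unevaluable:<field>"`` when a tested field
    is absent — absent statistics are never silently treated as failing
    values.
    """

    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


_TESTED_FIELDS = (
    "filter_status",
    "tlod",
    "nlod",
    "normal_depth",
    "tumor_depth",
    "tumor_alt_count",
    "normal_alt_count",
    "tumor_af",
)


def evaluate_filters(v: VariantRecord, t: FilterThresholds | None = None) -> FilterDecision:
    """Apply the eight variant-level predicates; all comparisons inclusive."""
    t = t or FilterThresholds()
    for name in _TESTED_FIELDS:
        if getattr(v, name) is None:
            return FilterDecision(False, f"unevaluable:{name}")
    if v.filter_status != frozenset({"PASS"}):
        return FilterDecision(False, "non-pass-filter")
    if v.tlod < t.min_tlod:
        return FilterDecision(False, "low-tlod")
    if v.nlod < t.min_nlod:
        return FilterDecision(False, "low-nlod")
    if v.normal_depth < t.min_normal_depth:
        return FilterDecision(False, "low-normal-depth")
    if v.tumor_depth < t.min_tumor_depth:
        return FilterDecision(False, "low-tumor-depth")
    if v.tumor_alt_count < t.min_tumor_alt:
        return FilterDecision(False, "low-tumor-alt")
    if v.normal_alt_count > t.max_normal_alt:
        return FilterDecision(False, "normal-alt-present")
    if v.tumor_af < t.min_tumor_af:
        return FilterDecision(False, "low-tumor-af")
    return FilterDecision(True)


def pass_variant_filters(v: VariantRecord, t: FilterThresholds | None = None) -> bool:
    """True iff the record passes all eight predicates (see evaluate_filters)."""
    return evaluate_filters(v, t).passed


def _none_if_missing_int(value) -> int | None:
    if value is None:
        return None
    value = int(value)
    # htslib missing-integer sentinels
    if value < 0:
        return None
    return value


def _none_if_missing_float(value) -> float | None:
    if value is None:
        return None
    value = float(value)
    if value != value:  # NaN
        return None
    return value


def _per_alt(value, alt_index: int, n_alt: int):
    """Pick the per-ALT component of a possibly scalar INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if len(value) == n_alt else value[0]
    try:  # numpy array
        if getattr(value, "ndim", 0) >= 1:
            flat = value.reshape(-1)
            return flat[alt_index] if flat.size == n_alt else flat[0]
    except Exception:
        pass
    return value


def _tumor_normal_indices(vcf, tumor_sample: str | None, normal_sample: str | None):
    samples = list(vcf.samples)
    if tumor_sample is None or normal_sample is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##tumor_sample=") and tumor_sample is None:
                tumor_sample = line.split("=", 1)[1].strip()
            elif line.startswith("##normal_sample=") and normal_sample is None:
                normal_sample = line.split("=", 1)[1].strip()
    if tumor_sample is None and "TUMOR" in samples:
        tumor_sample = "TUMOR"
    if normal_sample is None and "NORMAL" in samples:
        normal_sample = "NORMAL"
    if tumor_sample not in samples or normal_sample not in samples:
        raise ConfigurationError(
            f"cannot identify tumor/normal columns among samples {samples}; "
            "declare ##tumor_sample/##normal_sample or pass them explicitly"
        )
    return samples.index(tumor_sample), samples.index(normal_sample)


def read_somatic_vcf(
    path: str | Path,
    sample_id: str,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[VariantRecord]:
    """Read a MuTect2-dialect somatic VCF into variant records.

    Multi-allelic sites are split into one record per ALT allele, with
    AD/AF apportioned per allele.  The tumor allele fraction is taken
    from FORMAT/AF when present, otherwise computed as alt/depth.
    Missing caller statistics surface as ``None``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    ti, ni = _tumor_normal_indices(vcf, tumor_sample, normal_sample)
    records: list[VariantRecord] = []
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            alts = var.ALT
            n_alt = len(alts)
            filt = var.FILTER
            filter_status = (
                frozenset({"PASS"}) if filt is None else frozenset(filt.split(";"))
            )
            tlod_raw = var.INFO.get("TLOD")
            nlod_raw = var.INFO.get("NLOD")
            ad = var.format("AD")
            dp = var.format("DP")
            af = var.format("AF")
            for j, alt in enumerate(alts):
                t_alt = n_alt_count = t_dp = n_dp = None
                if ad is not None:
                    t_alt = _none_if_missing_int(ad[ti, 1 + j])
                    n_alt_count = _none_if_missing_int(ad[ni, 1 + j])
                if dp is not None:
                    t_dp = _none_if_missing_int(dp[ti, 0])
                    n_dp = _none_if_missing_int(dp[ni, 0])
                elif ad is not None:
                    t_dp = _none_if_missing_int(max(0, ad[ti].clip(min=0).sum()))
                    n_dp = _none_if_missing_int(max(0, ad[ni].clip(min=0).sum()))
                t_af = None
                if af is not None:
                    t_af = _none_if_missing_float(_per_alt(af[ti], j, n_alt))
                if t_af is None and t_alt is not None and t_dp:
                    t_af = t_alt / t_dp
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        filter_status=filter_status,
                        tlod=_none_if_missing_float(_per_alt(tlod_raw, j, n_alt)),
                        nlod=_none_if_missing_float(nlod_raw),
                        tumor_depth=t_dp,
                        normal_depth=n_dp,
                        tumor_alt_count=t_alt,
                        normal_alt_count=n_alt_count,
                        tumor_af=t_af,
                    )
                )
    except Exception as exc:
        if isinstance(exc, (VcfParseError, ConfigurationError)):
            raise
        raise VcfParseError(
            f"malformed VCF {path} near record {record_no + 1}: {exc}"
        ) from exc
    return records


@dataclass
class CohortSelection:
    """Result of sample-level selection: retained records + audit trail."""

    retained: dict[str, list[VariantRecord]]
    exclusions: dict[str, str] = field(default_factory=dict)
    passing_counts: dict[str, int] = field(default_factory=dict)


def _coerce_metadata(meta) -> list[SampleMetadata]:
    if isinstance(meta, pd.DataFrame):
        rows = []
        for rec in meta.to_dict("records"):
            rows.append(
                SampleMetadata(
                    sample_id=str(rec["sample_id"]),
                    patient_id=str(rec["patient_id"]),
                    is_wga=bool(rec.get("is_wga", False)),
                    is_ffpe=bool(rec.get("is_ffpe", False)),
                    is_msi=bool(rec.get("is_msi", False)),
                    preference_rank=int(rec.get("preference_rank", 1)),
                )
            )
        return rows
    return list(meta)


def select_cohort(
    records: Mapping[str, Sequence[VariantRecord]],
    meta,
    t: FilterThresholds | None = None,
) -> CohortSelection:
    """Sample-level cohort selection with per-sample exclusion reasons.

    Order of exclusion: WGA/FFPE/MSI flags, then one sample per patient
    (lowest preference rank, ties by lexicographic sample id), then the
    minimum passing-variant count.  Retained samples carry only their
    filter-passing records.
    """
    t = t or FilterThresholds()
    meta_rows = _coerce_metadata(meta)
    by_id = {}
    for m in meta_rows:
        if m.sample_id in by_id:
            raise DataError(f"duplicate sample_id {m.sample_id!r} in metadata")
        by_id[m.sample_id] = m
    missing = set(records) - set(by_id)
    if missing:
        raise DataError(f"samples absent from metadata: {sorted(missing)}")

    exclusions: dict[str, str] = {}
    candidates: list[SampleMetadata] = []
    for sid in records:
        m = by_id[sid]
        if m.is_wga:
            exclusions[sid] = "wga"
        elif m.is_ffpe:
            exclusions[sid] = "ffpe"
        elif m.is_msi:
            exclusions[sid] = "msi"
        else:
            candidates.append(m)

    chosen: dict[str, SampleMetadata] = {}
    for m in candidates:
        cur = chosen.get(m.patient_id)
        if cur is None or (m.preference_rank, m.sample_id) < (
            cur.preference_rank,
            cur.sample_id,
        ):
            chosen[m.patient_id] = m
    kept_ids = {m.sample_id for m in chosen.values()}
    for m in candidates:
        if m.sample_id not in kept_ids:
            exclusions[m.sample_id] = "duplicate-patient"

    retained: dict[str, list[VariantRecord]] = {}
    passing_counts: dict[str, int] = {}
    for sid in records:
        if sid not in kept_ids:
            continue
        passing = [v for v in records[sid] if evaluate_filters(v, t).passed]
        passing_counts[sid] = len(passing)
        if len(passing) < t.min_variants_per_sample:
            exclusions[sid] = "below-min-variants"
        else:
            retained[sid] = passing
    return CohortSelection(retained, exclusions, passing_counts)


def is_deleterious(v: VariantRecord) -> bool:
    """Deleterious-mutation rule.

    An exonic SNV labeled Pathogenic/Likely Pathogenic, any nonsense SNV
    (regardless of label), or an indel labeled Pathogenic/Likely
    Pathogenic.  Unannotated records are not deleterious.
    """
    label = v.pathogenicity_label
    consequence = (v.consequence or "").lower()
    if v.is_indel:
        return label in PATHOGENIC_LABELS
    if v.is_snv:
        if "nonsense" in consequence or "stopgain" in consequence:
            return True
        if "exonic" in consequence and label in PATHOGENIC_LABELS:
            return True
    return False


def ercc_mutation_status(
    records: Iterable[VariantRecord],
    genes: frozenset[str] | set[str] = DEFAULT_ERCC_GENES,
) -> str:
    """Per-sample ERCC-family mutation label.

    ``"none"`` without deleterious hits, the gene name for exactly one
    deleteriously mutated family member, ``"multi"`` for two or more
    distinct genes.
    """
    hit = {v.gene for v in records if v.gene in genes and is_deleterious(v)}
    if not hit:
        return "none"
    if len(hit) == 1:
        return next(iter(hit))
    return "multi"


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Tab-separated metadata table -> validated DataFrame."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id"}
    if not required <= set(df.columns):
        raise FormatErrorFor(path, required - set(df.columns))
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample_id {dup!r} in metadata")
    for col, default in (
        ("is_wga", False),
        ("is_ffpe", False),
        ("is_msi", False),
        ("preference_rank", 1),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def FormatErrorFor(path, cols):  # small helper, keeps the message uniform
    from .errors import FormatError

    return FormatError(f"{path}: missing required columns {sorted(cols)}")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated pathogenicity annotation keyed by (chrom,pos,ref,alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise FormatErrorFor(path, required - set(df.columns))
    return df


def annotate_records(
    records: Iterable[VariantRecord], annotations: pd.DataFrame
) -> list[VariantRecord]:
    """Attach gene/consequence/pathogenicity annotations by variant key."""
    idx = {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]).upper(), str(r["alt"]).upper()): r
        for r in annotations.to_dict("records")
    }
    out = []
    for v in records:
        ann = idx.get(v.key)
        if ann is None:
            out.append(v)
        else:
            out.append(
                replace(
                    v,
                    gene=ann.get("gene") if pd.notna(ann.get("gene")) else None,
                    consequence=ann.get("consequence")
                    if pd.notna(ann.get("consequence"))
                    else None,
                    pathogenicity_label=ann.get("pathogenicity_label")
                    if pd.notna(ann.get("pathogenicity_label"))
                    else None,
                )
            )
    return out


class VariantFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around the eight-predicate stringent filter.

    Parameters mirror :class:`FilterThresholds` so the filter composes
    with sklearn model-selection utilities.
    """

    def __init__(
        self,
        min_tlod: float = 6.0,
        min_nlod: float = 3.0,
        min_normal_depth: int = 15,
        min_tumor_depth: int = 20,
        min_tumor_alt: int = 5,
        max_normal_alt: int = 0,
        min_tumor_af: float = 0.05,
        min_variants_per_sample: int = 50,
    ):
        self.min_tlod = min_tlod
        self.min_nlod = min_nlod
        self.min_normal_depth = min_normal_depth
        self.min_tumor_depth = min_tumor_depth
        self.min_tumor_alt = min_tumor_alt
        self.max_normal_alt = max_normal_alt
        self.min_tumor_af = min_tumor_af
        self.min_variants_per_sample = min_variants_per_sample

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(**self.get_params())

    def fit(self, X=None, y=None):
        self.thresholds_ = self.thresholds()
        return self

    def transform(self, X):
        """Filter records: a sequence of records, or a mapping by sample."""
        if not hasattr(self, "thresholds_"):
            self.fit()
        t = self.thresholds_
        if isinstance(X, Mapping):
            return {
                sid: [v for v in vs if evaluate_filters(v, t).passed]
                for sid, vs in X.items()
            }
        return [v for v in X if evaluate_filters(v, t).passed]
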
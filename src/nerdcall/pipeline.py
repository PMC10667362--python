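"""End-to-end orchestration: VCFs -> filters -> catalog -> refit -> calls.

This is the programmatic equivalent of running the CLI subcommands in
sequence, returning every intermediate product for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import decide
from .catalog import ReferenceGenome, build_catalog
from .decide import ResponderCaller
from .errors import ConfigurationError
from .refit import SignatureRefitter
from .variants import (
    CohortSelection,
    FilterThresholds,
    annotate_records,
    ercc_mutation_status,
    read_somatic_vcf,
    select_cohort,
)


@dataclass
class PipelineResult:
    """All cohort-level products of one pipeline run."""

    selection: CohortSelection
    catalogs: pd.DataFrame
    exposures: pd.DataFrame
    calls: pd.DataFrame
    enrichment: decide.EnrichmentResult
    summary: dict
    ptgr1_cutoff: float


def run_cohort(
    vcfs: dict[str, str | Path] | None,
    metadata: pd.DataFrame,
    reference,
    signatures,
    cohort_expression: pd.DataFrame,
    cellline_expression: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    records: dict | None = None,
    thresholds: FilterThresholds | None = None,
    id8_threshold: float = decide.DEFAULT_ID8_THRESHOLD,
    reference_line: str = decide.DEFAULT_REFERENCE_LINE,
    full_denominator: int | None = None,
) -> PipelineResult:
    """Run the whole calling pipeline over one cohort.

    ``vcfs`` maps sample ids to VCF paths; alternatively pre-parsed
    ``records`` (sample id -> list of VariantRecord) may be supplied.
    Expression tables must share a normalization (see
    :func:`nerdcall.decide.calibrate_ptgr1_cutoff`).
    """
    if records is None:
        if vcfs is None:
            raise ConfigurationError("either vcfs or records must be given")
        records = {
            sid: read_somatic_vcf(path, sid) for sid, path in vcfs.items()
        }
    if annotations is not None and len(annotations):
        records = {
            sid: annotate_records(recs, annotations) for sid, recs in records.items()
        }
    thresholds = thresholds or FilterThresholds()
    selection = select_cohort(records, metadata, thresholds)

    genome = (
        reference
        if isinstance(reference, ReferenceGenome)
        else ReferenceGenome(reference)
    )
    catalogs = build_catalog(selection.retained, genome)
    refitter = SignatureRefitter(signatures=signatures).fit()
    exposures = refitter.refit(catalogs)
    if "ID8" not in exposures.columns:
        raise ConfigurationError("signature matrix does not contain ID8")

    cohort_expression = decide.with_log_values(cohort_expression)
    cellline_expression = decide.with_log_values(cellline_expression)
    expr = cohort_expression.set_index(
        [cohort_expression["entity_id"], cohort_expression["gene"]]
    )
    rows = []
    for sid in catalogs.index:
        try:
            ptgr1 = float(expr.loc[(sid, "PTGR1"), "log_value"])
        except KeyError as exc:
            raise ConfigurationError(f"no PTGR1 expression for sample {sid!r}") from exc
        rows.append(
            {
                "sample_id": sid,
                "id8": float(exposures.loc[sid, "ID8"]),
                "ptgr1": ptgr1,
                "ercc_status": ercc_mutation_status(selection.retained[sid]),
            }
        )
    features = pd.DataFrame(rows).set_index("sample_id")

    caller = ResponderCaller(
        id8_threshold=id8_threshold, reference_line=reference_line
    ).fit(cellline_expression, cohort_units=cohort_expression.attrs.get("units"))
    calls = caller.call(features)
    enrichment = decide.ercc_enrichment(calls)
    summary = decide.summarize_cohort(calls, full_denominator=full_denominator)
    return PipelineResult(
        selection=selection,
        catalogs=catalogs,
        exposures=exposures,
        calls=calls,
        enrichment=enrichment,
        summary=summary,
        ptgr1_cutoff=caller.ptgr1_cutoff_,
    )
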
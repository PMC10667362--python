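"""Fully synthetic cohorts with a complete ground-truth ledger.

The simulator emulates the statistical structure of the study inputs —
somatic indel calls drawn from signature-exposure mixtures, realized as
MuTect2-dialect VCFs against an engineered reference, with sample
metadata, pathogenicity annotations and expression tables — so that
every pipeline stage is testable without any external download.

The reference is not random-only: for every one of the 83 indel
channels it carries engineered, self-guarded loci (homopolymer runs,
tandem repeats, microhomology-flanked unique segments) at which a
variant of exactly that channel can be realized.  Guard bases around
each motif make classification independent of the surrounding spacer
sequence, so realize -> normalize -> classify round-trips by
construction.  Everything emitted is recorded in a truth ledger and the
whole cohort is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ReferenceGenome
from .channels import ID83_CHANNELS, ID83_LABELS, ChannelId
from .errors import GenerationError
from .variants import VariantRecord

FAIL_PREDICATES = (
    "non-pass-filter",
    "low-tlod",
    "low-nlod",
    "low-normal-depth",
    "low-tumor-depth",
    "low-tumor-alt",
    "normal-alt-present",
    "low-tumor-af",
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Burdens are per-sample indel counts drawn from a Poisson law;
    exposure profiles are signature-mixture weights (summing to one) for
    the NER-deficient and background groups; PTGR1 is simulated directly
    in log2(FPKM + 1) units with two group means and a common spread.
    ``fraction_filter_fail`` of each sample's records are *planned* to
    violate exactly one named filter predicate each (exact counts, not
    sampled), so filter tests are deterministic.
    """

    seed: int = 0
    n_samples: int = 40
    n_contigs: int = 3
    contig_length: int = 30_000  # minimum; grown to fit engineered loci
    loci_per_channel: int = 40
    mean_burden: float = 150.0
    nerd_fraction: float = 0.3
    nerd_profile: dict = field(
        default_factory=lambda: {"ID1": 0.35, "ID2": 0.25, "ID8": 0.40}
    )
    background_profile: dict = field(
        default_factory=lambda: {"ID1": 0.54, "ID2": 0.44, "ID8": 0.02}
    )
    fraction_filter_fail: float = 0.1
    ptgr1_means: tuple = (6.0, 3.0)  # (responder-like, low), log2(FPKM+1)
    ptgr1_sd: float = 0.8
    ptgr1_high_fraction: float = 0.6
    ptgr1_cellline_reference_value: float = 4.5  # planted A498 expression
    ercc_mutation_rates: dict = field(
        default_factory=lambda: {"nerd": 0.25, "background": 0.02}
    )
    n_snvs_per_sample: int = 5
    n_wga: int = 0
    n_ffpe: int = 0
    n_msi: int = 0
    n_extra_patient_samples: int = 0
    n_low_burden: int = 0
    low_burden: int = 20

    def validate(self) -> None:
        for name in ("nerd_fraction", "fraction_filter_fail", "ptgr1_high_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1.0000001:
                raise ValueError(f"{name} must lie in [0, 1]")
        for prof in (self.nerd_profile, self.background_profile):
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError("exposure profile weights must sum to 1")


def _rand_base(rng: np.random.Generator, exclude: str = "") -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _rand_unit(rng: np.random.Generator, n: int) -> str:
    while True:
        u = _rand_seq(rng, n)
        if _is_primitive(u):
            return u


def _motif_for_channel(ch: ChannelId, rng: np.random.Generator):
    """(motif string, offset of indel start within motif, indel seq, kind).

    Motifs are self-guarded: the bases flanking the engineered context
    are chosen so that left-alignment cannot shift past the motif and
    context counting stops inside it, whatever the surrounding sequence.
    """
    if ch.context.startswith("homopolymer"):
        pyr = ch.context[-1]
        base = {"C": "CG", "T": "AT"}[pyr][int(rng.integers(2))]
        if ch.kind == "Del":
            run = int(ch.count_bin) if ch.count_bin != "6+" else int(rng.integers(6, 9))
        else:
            run = int(ch.count_bin) if ch.count_bin != "5+" else int(rng.integers(5, 8))
        g1 = _rand_base(rng, exclude=base)
        g2 = _rand_base(rng, exclude=base)
        return g1 + base * run + g2, 1, base, ("deletion" if ch.kind == "Del" else "insertion")
    size = int(ch.length_bin) if ch.length_bin != "5+" else int(rng.integers(5, 8))
    if ch.context == "repeat":
        if ch.kind == "Del":
            copies = int(ch.count_bin) if ch.count_bin != "6+" else int(rng.integers(6, 9))
        else:
            copies = int(ch.count_bin) if ch.count_bin != "5+" else int(rng.integers(5, 8))
        unit = _rand_unit(rng, size)
        g1 = _rand_base(rng, exclude=unit[-1])
        g2 = _rand_base(rng, exclude=unit[0])
        return (
            g1 + unit * copies + g2,
            1,
            unit,
            ("deletion" if ch.kind == "Del" else "insertion"),
        )
    # microhomology deletion
    mh = int(ch.count_bin) if ch.count_bin != "5+" else 5
    if ch.length_bin == "5+":
        size = int(rng.integers(max(6, mh + 1), 9))
    deleted = _rand_seq(rng, size)
    g1 = _rand_base(rng, exclude=deleted[-1])
    breaker = _rand_base(rng, exclude=deleted[mh])
    return g1 + deleted + deleted[:mh] + breaker, 1, deleted, "deletion"


def generate_reference(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[ReferenceGenome, dict]:
    """Engineered reference contigs plus a per-channel locus registry.

    The registry maps each channel label to a list of loci
    ``{"contig", "start", "kind", "seq"}`` (0-based start of the first
    inserted/deleted base) at which that channel can be realized.
    Reproducible from the seed; written as FASTA + .fai + JSON when
    ``out_dir`` is given.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    names = [f"chrS{i + 1}" for i in range(cfg.n_contigs)]
    parts: dict[str, list[str]] = {n: [_rand_seq(rng, 20)] for n in names}
    lengths = {n: 20 for n in names}
    registry: dict[str, list[dict]] = {lab: [] for lab in ID83_LABELS}
    turn = 0
    for ch in ID83_CHANNELS:
        for _ in range(cfg.loci_per_channel):
            contig = names[turn % len(names)]
            turn += 1
            spacer = _rand_seq(rng, int(rng.integers(8, 16)))
            motif, offset, seq, kind = _motif_for_channel(ch, rng)
            start = lengths[contig] + len(spacer) + offset
            parts[contig].append(spacer + motif)
            lengths[contig] += len(spacer) + len(motif)
            registry[ch.label].append(
                {"contig": contig, "start": int(start), "kind": kind, "seq": seq}
            )
    contigs = {}
    for n in names:
        seq = "".join(parts[n])
        if len(seq) < cfg.contig_length:
            seq += _rand_seq(rng, cfg.contig_length - len(seq))
        contigs[n] = seq
    genome = ReferenceGenome(contigs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "reference.fa"
        with open(fasta, "w") as fh:
            for n in names:
                fh.write(f">{n}\n")
                s = contigs[n]
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")
        import pyfaidx

        pyfaidx.Faidx(str(fasta))  # writes reference.fa.fai
        with open(out_dir / "loci.json", "w") as fh:
            json.dump(registry, fh)
    return genome, registry


def _draw_caller_stats(rng: np.random.Generator, fail: str | None = None) -> dict:
    """Caller statistics passing all eight predicates, or failing exactly one."""
    tumor_depth = int(rng.integers(40, 150))
    af = float(rng.uniform(0.10, 0.60))
    tumor_alt = max(5, int(round(af * tumor_depth)))
    stats = {
        "filter_status": frozenset({"PASS"}),
        "tlod": float(6.0 + rng.exponential(30.0)),
        "nlod": float(3.0 + rng.exponential(15.0)),
        "normal_depth": int(rng.integers(20, 80)),
        "tumor_depth": tumor_depth,
        "tumor_alt_count": tumor_alt,
        "normal_alt_count": 0,
        "tumor_af": None,  # recomputed below
    }
    if fail == "non-pass-filter":
        stats["filter_status"] = frozenset({"germline"})
    elif fail == "low-tlod":
        stats["tlod"] = float(rng.uniform(0.5, 5.9))
    elif fail == "low-nlod":
        stats["nlod"] = float(rng.uniform(0.5, 2.9))
    elif fail == "low-normal-depth":
        stats["normal_depth"] = int(rng.integers(1, 15))
    elif fail == "low-tumor-depth":
        stats["tumor_depth"] = int(rng.integers(10, 20))
        stats["tumor_alt_count"] = int(rng.integers(5, stats["tumor_depth"] + 1))
    elif fail == "low-tumor-alt":
        stats["tumor_alt_count"] = int(rng.integers(1, 5))
        stats["tumor_depth"] = int(rng.integers(30, 71))
    elif fail == "normal-alt-present":
        stats["normal_alt_count"] = int(rng.integers(1, 4))
    elif fail == "low-tumor-af":
        stats["tumor_alt_count"] = 5
        stats["tumor_depth"] = int(rng.integers(150, 301))
    elif fail is not None:
        raise GenerationError(f"unknown fail predicate {fail!r}")
    stats["tumor_af"] = round(stats["tumor_alt_count"] / stats["tumor_depth"], 4)
    return stats


def realize_variant(
    channel: ChannelId | str,
    ref_genome: ReferenceGenome,
    rng: np.random.Generator,
    registry: dict,
    sample_id: str = "S",
    fail_predicate: str | None = None,
) -> VariantRecord:
    """Emit a VCF-style record that classifies to exactly ``channel``.

    The locus is drawn from the engineered registry; caller statistics
    are drawn to pass every filter unless ``fail_predicate`` names the
    single predicate to violate.
    """
    label = channel.label if isinstance(channel, ChannelId) else str(channel)
    loci = registry.get(label)
    if not loci:
        raise GenerationError(f"no realizable locus for channel {label}")
    locus = loci[int(rng.integers(len(loci)))]
    chrom, start, seq = locus["contig"], locus["start"], locus["seq"]
    anchor = ref_genome.base(chrom, start - 1)
    if not anchor:
        raise GenerationError(f"locus for {label} lies at a contig edge")
    if locus["kind"] == "deletion":
        ref = ref_genome.seq(chrom, start - 1, start + len(seq))
        alt = anchor
    else:
        ref = anchor
        alt = anchor + seq
    stats = _draw_caller_stats(rng, fail_predicate)
    return VariantRecord(
        sample_id=sample_id, chrom=chrom, pos=start, ref=ref, alt=alt, **stats
    )


def realize_snv(
    ref_genome: ReferenceGenome,
    rng: np.random.Generator,
    sample_id: str = "S",
) -> VariantRecord:
    """A filter-passing SNV at a random position (ignored by the catalog)."""
    chrom = ref_genome.contigs[int(rng.integers(len(ref_genome.contigs)))]
    pos0 = int(rng.integers(50, ref_genome.length(chrom) - 50))
    ref = ref_genome.base(chrom, pos0)
    alt = _rand_base(rng, exclude=ref)
    stats = _draw_caller_stats(rng, None)
    return VariantRecord(
        sample_id=sample_id, chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, **stats
    )


def shifted_representations(
    chrom: str,
    start: int,
    seq: str,
    kind: str,
    ref_genome: ReferenceGenome,
    max_reps: int = 20,
) -> list[tuple[int, str, str]]:
    """All VCF (pos, REF, ALT) encodings of one physical indel.

    Starting from the left-aligned form, the anchor is slid rightward
    through the repeat tract as long as the representations stay
    equivalent.  Used to check that classification is
    representation-independent.
    """
    size = len(seq)
    reps: list[tuple[int, str, str]] = []
    if kind == "deletion":
        d = 0
        while len(reps) < max_reps:
            anchor = ref_genome.base(chrom, start + d - 1)
            if not anchor:
                break
            ref = ref_genome.seq(chrom, start + d - 1, start + d + size)
            reps.append((start + d, ref, anchor))
            if ref_genome.base(chrom, start + d) != ref_genome.base(
                chrom, start + d + size
            ) or ref_genome.base(chrom, start + d) == "":
                break
            d += 1
    else:
        d = 0
        cur = seq
        while len(reps) < max_reps:
            anchor = ref_genome.base(chrom, start + d - 1)
            if not anchor:
                break
            reps.append((start + d, anchor, anchor + cur))
            if ref_genome.base(chrom, start + d) != cur[0]:
                break
            cur = cur[1:] + cur[0]
            d += 1
    return reps


@dataclass
class SimulatedCohort:
    """Everything a simulated study emits, plus its truth ledger."""

    config: SimulationConfig
    reference: ReferenceGenome
    registry: dict
    records: dict[str, list[VariantRecord]]
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    cohort_expression: pd.DataFrame
    cellline_expression: pd.DataFrame
    variants_ledger: pd.DataFrame
    samples_ledger: pd.DataFrame
    paths: dict = field(default_factory=dict)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=nerdcall-simulate
##tumor_sample=TUMOR
##normal_sample=NORMAL
{contigs}##FILTER=<ID=germline,Description="Evidence of the variant in the matched normal">
##INFO=<ID=TLOD,Number=A,Type=Float,Description="Log odds that the variant is present in the tumor">
##INFO=<ID=NLOD,Number=1,Type=Float,Description="Log odds that the variant is absent from the normal">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_vcf(
    records: list[VariantRecord], ref_genome: ReferenceGenome, path: str | Path
) -> None:
    """Write records as a MuTect2-dialect VCF (tumor + normal columns)."""
    contig_lines = "".join(
        f"##contig=<ID={c},length={ref_genome.length(c)}>\n" for c in ref_genome.contigs
    )
    order = {c: i for i, c in enumerate(ref_genome.contigs)}
    recs = sorted(records, key=lambda v: (order.get(v.chrom, 99), v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contig_lines))
        for v in recs:
            filt = "PASS" if v.filter_status == frozenset({"PASS"}) else ";".join(
                sorted(v.filter_status)
            )
            info = f"TLOD={v.tlod:.2f};NLOD={v.nlod:.2f}"
            t_ref = v.tumor_depth - v.tumor_alt_count
            n_ref = v.normal_depth - v.normal_alt_count
            n_af = round(v.normal_alt_count / v.normal_depth, 4) if v.normal_depth else 0.0
            tumor = f"0/1:{t_ref},{v.tumor_alt_count}:{v.tumor_af:.4f}:{v.tumor_depth}"
            normal = f"0/0:{n_ref},{v.normal_alt_count}:{n_af:.4f}:{v.normal_depth}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}"
                f"\tGT:AD:AF:DP\t{tumor}\t{normal}\n"
            )


_DECOY_GENES = ("VHL", "PBRM1", "SETD2", "TTN", "BAP1", "MUC16")
_CELL_LINES = ("786O", "769P", "RXF393", "CAKI1", "ACHN", "SLR26")


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate a full synthetic cohort on disk.

    Writes reference FASTA (+.fai), per-sample VCFs under ``vcfs/``,
    metadata/annotation/expression TSVs, the truth ledgers and the
    config JSON.  Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "vcfs").mkdir(exist_ok=True)
    genome, registry = generate_reference(cfg, out_dir)

    ss = np.random.SeedSequence([int(cfg.seed), 1])
    rng_assign, rng_burden, rng_channel, rng_caller, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    sig_names = sorted(
        set(cfg.nerd_profile) | set(cfg.background_profile)
    )
    from .refit import toy_signature_matrix

    sigs = toy_signature_matrix()
    unknown = [s for s in sig_names if s not in sigs.columns]
    if unknown:
        raise GenerationError(f"profile names unknown signatures: {unknown}")
    sig_cols = {s: sigs[s].to_numpy(dtype=float) for s in sig_names}
    sig_cum = {s: np.cumsum(c) for s, c in sig_cols.items()}

    n = cfg.n_samples
    n_nerd = int(round(cfg.nerd_fraction * n))
    perm = rng_assign.permutation(n)
    nerd_set = {int(i) for i in perm[:n_nerd]}

    flagged = rng_assign.permutation(n)[: cfg.n_wga + cfg.n_ffpe + cfg.n_msi]
    wga_set = {int(i) for i in flagged[: cfg.n_wga]}
    ffpe_set = {int(i) for i in flagged[cfg.n_wga : cfg.n_wga + cfg.n_ffpe]}
    msi_set = {int(i) for i in flagged[cfg.n_wga + cfg.n_ffpe :]}
    unflagged = [i for i in range(n) if i not in wga_set | ffpe_set | msi_set]
    low_burden_set = set(
        int(i)
        for i in rng_assign.permutation(unflagged)[: cfg.n_low_burden]
    )

    samples: list[dict] = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        samples.append(
            {
                "sample_id": f"{pid}-T1",
                "patient_id": pid,
                "index": i,
                "preference_rank": 1,
                "is_wga": i in wga_set,
                "is_ffpe": i in ffpe_set,
                "is_msi": i in msi_set,
                "group": "nerd" if i in nerd_set else "background",
                "low_burden": i in low_burden_set,
            }
        )
    for j in range(cfg.n_extra_patient_samples):
        pid = f"P{(j % n) + 1:04d}"
        samples.append(
            {
                "sample_id": f"{pid}-T2",
                "patient_id": pid,
                "index": n + j,
                "preference_rank": 2,
                "is_wga": False,
                "is_ffpe": False,
                "is_msi": False,
                "group": "background",
                "low_burden": True,
            }
        )

    records: dict[str, list[VariantRecord]] = {}
    var_rows: list[dict] = []
    sample_rows: list[dict] = []
    ann_rows: list[dict] = []
    expr_rows: list[dict] = []
    fail_cycle = 0

    for s in samples:
        sid = s["sample_id"]
        profile = cfg.nerd_profile if s["group"] == "nerd" else cfg.background_profile
        weights = np.array([profile.get(name, 0.0) for name in sig_names])
        burden = (
            int(rng_burden.integers(5, cfg.low_burden + 1))
            if s["low_burden"]
            else int(rng_burden.poisson(cfg.mean_burden))
        )
        n_fail = int(round(cfg.fraction_filter_fail * burden))
        recs: list[VariantRecord] = []
        planted_exp = {name: 0 for name in sig_names}
        for k in range(burden):
            si = int(
                np.searchsorted(np.cumsum(weights), rng_channel.uniform(), side="right")
            )
            sig = sig_names[min(si, len(sig_names) - 1)]
            ci = int(
                np.searchsorted(sig_cum[sig], rng_channel.uniform(), side="right")
            )
            ci = min(ci, 82)
            label = ID83_LABELS[ci]
            fail = FAIL_PREDICATES[fail_cycle % 8] if k < n_fail else None
            if fail is not None:
                fail_cycle += 1
            v = realize_variant(label, genome, rng_caller, registry, sid, fail)
            recs.append(v)
            if fail is None:
                planted_exp[sig] += 1
            var_rows.append(
                {
                    "sample_id": sid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "kind": "indel",
                    "channel": label,
                    "signature": sig,
                    "fail_predicate": fail or "",
                }
            )
        # SNVs: never in the catalog; carriers for pathogenicity annotations
        snvs = [realize_snv(genome, rng_caller, sid) for _ in range(cfg.n_snvs_per_sample)]
        rate = cfg.ercc_mutation_rates.get(s["group"], 0.0)
        ercc_genes: list[str] = []
        if snvs and rng_assign.uniform() < rate:
            n_genes = 2 if rng_assign.uniform() < 0.15 else 1
            ercc_genes = list(
                rng_assign.choice(["ERCC2", "ERCC3", "ERCC6"], size=n_genes, replace=False)
            )
        for j, v in enumerate(snvs):
            recs.append(v)
            ann = None
            if j < len(ercc_genes):
                ann = {
                    "gene": ercc_genes[j],
                    "consequence": "exonic SNV"
                    if rng_assign.uniform() < 0.7
                    else "nonsense SNV",
                    "pathogenicity_label": "Pathogenic"
                    if rng_assign.uniform() < 0.5
                    else "Likely Pathogenic",
                }
            elif rng_assign.uniform() < 0.7:
                ann = {
                    "gene": _DECOY_GENES[int(rng_assign.integers(len(_DECOY_GENES)))],
                    "consequence": "exonic SNV",
                    "pathogenicity_label": "Benign"
                    if rng_assign.uniform() < 0.5
                    else "Uncertain Significance",
                }
            if ann is not None:
                ann_rows.append(
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, **ann}
                )
            var_rows.append(
                {
                    "sample_id": sid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "kind": "snv",
                    "channel": "",
                    "signature": "",
                    "fail_predicate": "",
                }
            )
        records[sid] = recs

        high = bool(rng_expr.uniform() < cfg.ptgr1_high_fraction)
        mean = cfg.ptgr1_means[0] if high else cfg.ptgr1_means[1]
        ptgr1_log = max(0.0, float(rng_expr.normal(mean, cfg.ptgr1_sd)))
        expr_rows.append(
            {
                "entity_id": sid,
                "gene": "PTGR1",
                "raw_value": round(2.0**ptgr1_log - 1.0, 6),
                "units": "FPKM",
            }
        )
        sample_rows.append(
            {
                "sample_id": sid,
                "patient_id": s["patient_id"],
                "is_wga": s["is_wga"],
                "is_ffpe": s["is_ffpe"],
                "is_msi": s["is_msi"],
                "preference_rank": s["preference_rank"],
                "group": s["group"],
                "burden": burden,
                "n_fail_planted": n_fail,
                **{f"exp_{name}": planted_exp[name] for name in sig_names},
                "ptgr1_log": round(ptgr1_log, 6),
                "ptgr1_high": high,
                "ercc_genes": ",".join(sorted(ercc_genes)),
            }
        )

    # calibration panel: A498 exactly at the planted cutoff, others around it
    cell_rows = [
        {
            "entity_id": "A498",
            "gene": "PTGR1",
            "raw_value": round(2.0**cfg.ptgr1_cellline_reference_value - 1.0, 6),
            "units": "FPKM",
        }
    ]
    for line in _CELL_LINES:
        val = max(0.0, float(rng_expr.normal(3.5, 1.2)))
        cell_rows.append(
            {
                "entity_id": line,
                "gene": "PTGR1",
                "raw_value": round(2.0**val - 1.0, 6),
                "units": "FPKM",
            }
        )

    metadata = pd.DataFrame(
        [
            {
                k: s[k]
                for k in (
                    "sample_id",
                    "patient_id",
                    "is_wga",
                    "is_ffpe",
                    "is_msi",
                    "preference_rank",
                )
            }
            for s in samples
        ]
    )
    annotations = pd.DataFrame(
        ann_rows, columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "pathogenicity_label"]
    )
    cohort_expression = pd.DataFrame(expr_rows)
    cellline_expression = pd.DataFrame(cell_rows)
    variants_ledger = pd.DataFrame(var_rows)
    samples_ledger = pd.DataFrame(sample_rows)

    paths = {"reference": out_dir / "reference.fa", "vcf_dir": out_dir / "vcfs"}
    for sid, recs in records.items():
        p = out_dir / "vcfs" / f"{sid}.vcf"
        write_vcf(recs, genome, p)
    for name, df in (
        ("metadata.tsv", metadata),
        ("annotations.tsv", annotations),
        ("expression_cohort.tsv", cohort_expression),
        ("expression_celllines.tsv", cellline_expression),
        ("ledger_variants.tsv", variants_ledger),
        ("ledger_samples.tsv", samples_ledger),
    ):
        df.to_csv(out_dir / name, sep="\t", index=False)
        paths[name] = out_dir / name
    with open(out_dir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, default=list)
    paths["config.json"] = out_dir / "config.json"

    return SimulatedCohort(
        config=cfg,
        reference=genome,
        registry=registry,
        records=records,
        metadata=metadata,
        annotations=annotations,
        cohort_expression=cohort_expression,
        cellline_expression=cellline_expression,
        variants_ledger=variants_ledger,
        samples_ledger=samples_ledger,
        paths=paths,
    )


def draw_catalogs(
    sigs: pd.DataFrame,
    profiles: np.ndarray | list,
    burdens: np.ndarray | list,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Catalog counts drawn directly from the generative mixture model.

    For statistical recovery experiments the variant-realization and VCF
    plumbing is unnecessary: each sample's 83-channel counts are a
    multinomial draw of size ``burden`` from its signature mixture
    ``sigs @ w``.  Returns samples x 83 counts in canonical order.
    """
    S = sigs.loc[list(ID83_LABELS)].to_numpy(dtype=float)
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    burdens = np.asarray(burdens, dtype=int)
    rows = np.empty((len(burdens), 83), dtype=np.int64)
    for i, (w, b) in enumerate(zip(profiles, burdens)):
        p = S @ w
        p = p / p.sum()
        rows[i] = rng.multinomial(int(b), p)
    return pd.DataFrame(
        rows, index=[f"sim{i}" for i in range(len(burdens))], columns=list(ID83_LABELS)
    )
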
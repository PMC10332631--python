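"""Construction of phylogenetic sequence datasets and external-tool manifests.

Four dataset families: (1) the full ligase/octanoyltransferase superset
rooted by biotin ligase BirA; (2) clade-3 ligase variants with/without
LipM octanoyltransferases and circularly permuted ligases, rooted by
classical clade-2 ligases; (3) single-copy LipS1+LipS2 concatenations;
(4) individual LipS1 and LipS2 sets rooted by biotin synthase BioB.

Sequence-level normalizations implemented here: concatenation of
syntenic LplA+LplB gene pairs into the fused Lpl(AB) domain order,
rotation of circularly permuted Lpl(BA) fusions back into A-then-B
order (cp normalization), and greedy similarity clustering to thin
redundant sequences while keeping diversity.  Alignment, trimming and
tree inference are external tools; this module only emits exact
command manifests for them.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DomainHit,
    DomainOrder,
    FunctionalAnnotation,
    GeneCluster,
    GenomeProfile,
    Label,
    PhyloRecord,
    Provenance,
)

logger = logging.getLogger(__name__)

DATASET_NAMES = (
    "full_ligase_transferase",
    "clade3_no_LipM_no_cp",
    "clade3_with_LipM",
    "clade3_with_cp",
    "lipS1S2_concat",
    "lipS1_rooted",
    "lipS2_rooted",
)

#: Records shorter than this fraction of the within-label median length
#: are treated as incomplete and excluded where a completeness filter
#: applies.
COMPLETENESS_FRACTION = 0.6

#: Records shorter than this fraction of the longest same-dataset record
#: are aligned in a second pass (added to the full-length alignment
#: keeping its length) rather than in the primary alignment.
FRAGMENT_FRACTION = 0.8


# ---------------------------------------------------------------------------
# Record-level operations


def concat_syntenic_pair(
    genome_id: str,
    annotations: Mapping[str, FunctionalAnnotation],
    clusters: Sequence[GeneCluster],
    sequences: Mapping[str, str],
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> PhyloRecord | None:
    """Concatenate a syntenic LplA(catalytic) + LplB gene pair into A-then-B order.

    The pair must share a gene cluster, except for whitelisted genomes
    whose (biochemically characterized) bipartite ligase is kept despite
    the genes not forming a cluster.  Returns None when no unambiguous
    pair exists.
    """
    def split_ligases(pids):
        a = sorted(p for p in pids if annotations[p].label is Label.LPL
                   and not annotations[p].has_lplB_domain)
        b = sorted(p for p in pids if annotations[p].label is Label.LPLB)
        return a, b

    pairs: list[tuple[str, str]] = []
    for cluster in clusters:
        a_members, b_members = split_ligases(
            [p for p in cluster.protein_ids() if p in annotations]
        )
        if len(a_members) == 1 and len(b_members) == 1:
            pairs.append((a_members[0], b_members[0]))
        elif a_members and b_members:
            logger.warning("%s: ambiguous LplA/LplB pairing in one cluster; skipped", genome_id)
            return None
    if not pairs and genome_id in set(whitelist):
        a_all, b_all = split_ligases(annotations.keys())
        if len(a_all) == 1 and len(b_all) == 1:
            pairs = [(a_all[0], b_all[0])]
    if len(pairs) != 1:
        if len(pairs) > 1:
            logger.warning("%s: %d candidate LplA/LplB pairs; skipped", genome_id, len(pairs))
        return None
    pid_a, pid_b = pairs[0]
    seq_a, seq_b = sequences[pid_a], sequences[pid_b]
    return PhyloRecord(
        record_id=f"{genome_id}|{pid_a}+{pid_b}",
        sequence=seq_a + seq_b,
        partitions=(
            ("LplA", 1, len(seq_a)),
            ("LplB", len(seq_a) + 1, len(seq_a) + len(seq_b)),
        ),
        provenance=Provenance.CONCAT_SYNTENIC,
        label=Label.LPL,
    )


def cp_boundary_from_envelopes(lplb_hit: DomainHit, catalytic_hit: DomainHit) -> int:
    """Split point for a permuted Lpl(BA): midpoint of the inter-envelope gap."""
    if lplb_hit.env_to >= catalytic_hit.env_from:
        raise ValueError("expected the accessory envelope to precede the catalytic envelope")
    return (lplb_hit.env_to + catalytic_hit.env_from) // 2


def cp_normalize(
    record: PhyloRecord,
    boundary: int,
    domain_order: DomainOrder = DomainOrder.B_THEN_A,
) -> PhyloRecord:
    """Rotate a circularly permuted B-then-A fusion into canonical A-then-B order.

    Output is ``s[boundary+1..n] + s[1..boundary]`` (1-based); length is
    preserved and the two partitions record the rejoined segments.
    Records already in A-then-B order pass through unchanged.
    """
    if domain_order is DomainOrder.A_THEN_B:
        return record
    n = len(record.sequence)
    if not 0 < boundary < n:
        raise ValueError(f"boundary {boundary} outside (0, {n})")
    s = record.sequence
    rotated = s[boundary:] + s[:boundary]
    return PhyloRecord(
        record_id=record.record_id,
        sequence=rotated,
        partitions=(("LplA", 1, n - boundary), ("LplB", n - boundary + 1, n)),
        provenance=Provenance.CP_NORMALIZED,
        label=record.label,
    )


def concat_lipS1S2(
    profile: GenomeProfile,
    annotations: Mapping[str, FunctionalAnnotation],
    sequences: Mapping[str, str],
    median_lengths: Mapping[Label, float] | None = None,
) -> PhyloRecord | None:
    """Concatenate LipS1+LipS2 for genomes with exactly one copy of each.

    The single-copy requirement excludes paralogous sequences; when
    cohort-wide median lengths are given, subunits shorter than 60% of
    the within-label median are treated as incomplete and the genome is
    dropped.
    """
    if profile.count(Label.LIPS1) != 1 or profile.count(Label.LIPS2) != 1:
        return None
    pid_s1 = next(p for p, a in sorted(annotations.items()) if a.label is Label.LIPS1)
    pid_s2 = next(p for p, a in sorted(annotations.items()) if a.label is Label.LIPS2)
    seq1, seq2 = sequences[pid_s1], sequences[pid_s2]
    if median_lengths is not None:
        for lab, seq in ((Label.LIPS1, seq1), (Label.LIPS2, seq2)):
            med = median_lengths.get(lab)
            if med and len(seq) < COMPLETENESS_FRACTION * med:
                logger.warning(
                    "%s: %s sequence incomplete (%d < %.0f); excluded",
                    profile.genome_id, lab.value, len(seq), COMPLETENESS_FRACTION * med,
                )
                return None
    return PhyloRecord(
        record_id=f"{profile.genome_id}|{pid_s1}+{pid_s2}",
        sequence=seq1 + seq2,
        partitions=(
            ("LipS1", 1, len(seq1)),
            ("LipS2", len(seq1) + 1, len(seq1) + len(seq2)),
        ),
        provenance=Provenance.CONCAT_LIPS1S2,
        label=Label.LIPS1,
    )


def median_label_lengths(
    annotations: Mapping[str, FunctionalAnnotation], sequences: Mapping[str, str]
) -> dict[Label, float]:
    by_label: dict[Label, list[int]] = {}
    for pid, ann in annotations.items():
        if ann.label is not Label.NONE and pid in sequences:
            by_label.setdefault(ann.label, []).append(len(sequences[pid]))
    return {lab: float(statistics.median(v)) for lab, v in by_label.items()}


# ---------------------------------------------------------------------------
# Similarity clustering


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_identity(a: str, b: str, k: int = 4) -> float:
    """Alignment-free identity estimate: Jaccard similarity of k-mer sets."""
    ka, kb = _kmers(a, k), _kmers(b, k)
    if not ka or not kb:
        return 1.0 if a == b else 0.0
    return len(ka & kb) / len(ka | kb)


def cluster_by_similarity(
    records: Sequence[PhyloRecord],
    identity_threshold: float = 0.7,
    k: int = 4,
) -> list[PhyloRecord]:
    """Greedy incremental clustering; returns cluster founders.

    Records are visited longest-first (ties by record_id); each record
    joins the first existing representative it matches at or above the
    identity threshold, otherwise it founds a new cluster.  At a
    threshold of 1.0 only exact duplicate sequences are merged.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))
    reps: list[PhyloRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            if identity_threshold >= 1.0:
                same = rec.sequence == rep.sequence
            else:
                same = kmer_identity(rec.sequence, rep.sequence, k) >= identity_threshold
            if same:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class DatasetManifest:
    """Per-record inclusion ledger for one built dataset."""

    dataset: str
    entries: list[tuple[str, bool, str]] = field(default_factory=list)  # (id, included, reason)

    def add(self, record_id: str, included: bool, reason: str) -> None:
        self.entries.append((record_id, included, reason))

    @property
    def n_included(self) -> int:
        return sum(1 for _, inc, _ in self.entries if inc)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["record_id\tincluded\treason"]
        lines += [f"{rid}\t{int(inc)}\t{reason}" for rid, inc, reason in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RecordPool:
    """All record families a dataset build can draw from.

    ``ligases`` holds native fused ligases, syntenic concatenations and
    cp-normalized records; ``lipB``/``lipM`` the octanoyltransferases;
    ``lipS1S2`` the concatenated synthase pairs; ``lipS1``/``lipS2`` the
    individual subunits; ``outgroups`` maps outgroup family name
    (``BirA``, ``BioB``, ``clade2``) to records.
    """

    ligases: list[PhyloRecord] = field(default_factory=list)
    lipB: list[PhyloRecord] = field(default_factory=list)
    lipM: list[PhyloRecord] = field(default_factory=list)
    lipS1S2: list[PhyloRecord] = field(default_factory=list)
    lipS1: list[PhyloRecord] = field(default_factory=list)
    lipS2: list[PhyloRecord] = field(default_factory=list)
    outgroups: dict[str, list[PhyloRecord]] = field(default_factory=dict)


def build_dataset(
    name: str, pool: RecordPool
) -> tuple[list[PhyloRecord], DatasetManifest]:
    """Select and order the records of one named dataset.

    Every candidate record is accounted for in the manifest, included or
    excluded with a reason; outgroup records are appended last for the
    rooted datasets.  Raises on an empty selection.
    """
    if name not in DATASET_NAMES:
        raise ValueError(f"unknown dataset {name!r}; expected one of {DATASET_NAMES}")
    manifest = DatasetManifest(dataset=name)
    selected: list[PhyloRecord] = []

    def take(rec: PhyloRecord, reason: str) -> None:
        selected.append(rec)
        manifest.add(rec.record_id, True, reason)

    def drop(rec: PhyloRecord, reason: str) -> None:
        manifest.add(rec.record_id, False, reason)

    if name == "full_ligase_transferase":
        for rec in pool.ligases:
            take(rec, f"ligase:{rec.provenance.value}")
        for rec in pool.lipB:
            take(rec, "octanoyltransferase_LipB")
        for rec in pool.lipM:
            take(rec, "octanoyltransferase_LipM")
        outgroup = "BirA"
    elif name.startswith("clade3"):
        with_lipm = name == "clade3_with_LipM"
        with_cp = name == "clade3_with_cp"
        for rec in pool.ligases:
            if rec.provenance is Provenance.CP_NORMALIZED and not with_cp:
                drop(rec, "excluded_cp_normalized")
            else:
                take(rec, f"ligase:{rec.provenance.value}")
        for rec in pool.lipM:
            if with_lipm:
                take(rec, "octanoyltransferase_LipM")
            else:
                drop(rec, "excluded_LipM")
        outgroup = "clade2"
    elif name == "lipS1S2_concat":
        for rec in pool.lipS1S2:
            take(rec, "single_copy_concat")
        outgroup = None
    elif name == "lipS1_rooted":
        for rec in pool.lipS1:
            take(rec, "LipS1_single_copy")
        outgroup = "BioB"
    else:  # lipS2_rooted
        for rec in pool.lipS2:
            take(rec, "LipS2_single_copy")
        outgroup = "BioB"

    if outgroup is not None:
        for rec in pool.outgroups.get(outgroup, []):
            take(rec, f"outgroup_{outgroup}")
    if not selected:
        raise ValueError(f"dataset {name!r} selected no records")
    return selected, manifest


def write_fasta(records: Sequence[PhyloRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description=r.provenance.value)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_partition_tsv(records: Sequence[PhyloRecord], path: str | Path) -> None:
    lines = ["record_id\tpartition\tstart\tend"]
    for r in records:
        for pname, start, end in r.partitions:
            lines.append(f"{r.record_id}\t{pname}\t{start}\t{end}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# External-tool command manifests


@dataclass
class PhyloToolConfig:
    """Parameters for the external align/trim/tree steps.

    Defaults: BMGE entropy threshold 0.95, minimum block length 1,
    BLOSUM30 matrix; IQ-TREE with automatic model selection, SH-aLRT and
    ultrafast bootstrap at 2,000 replicates each plus aBayes supports.
    """

    aligner: str = "mafft"
    aligner_args: str = "--auto"
    entropy_threshold: float = 0.95
    min_length: int = 1
    matrix: str = "BLOSUM30"
    model_selection: bool = True
    sh_alrt_replicates: int = 2000
    ufboot_replicates: int = 2000
    abayes: bool = True
    seed: int = 1


def emit_tool_manifest(
    dataset_name: str,
    records: Sequence[PhyloRecord],
    config: PhyloToolConfig | None = None,
    workdir: str = ".",
) -> list[str]:
    """Ordered external commands to take one dataset from FASTA to tree.

    Short records (< 80% of the longest record) are aligned in a second
    MAFFT pass with ``--add-fragments --keeplength`` so incomplete or
    single-domain sequences (e.g. LipB/LipM among two-domain ligases) do
    not erode the full-length alignment.  Nothing is executed here.
    """
    cfg = config or PhyloToolConfig()
    base = f"{workdir}/{dataset_name}"
    max_len = max((len(r) for r in records), default=0)
    fragments = [r for r in records if len(r) < FRAGMENT_FRACTION * max_len]
    cmds: list[str] = []
    if fragments:
        cmds.append(
            f"{cfg.aligner} {cfg.aligner_args} {base}.full.faa > {base}.full.aln.faa"
        )
        cmds.append(
            f"{cfg.aligner} --add-fragments {base}.fragments.faa --keeplength "
            f"{base}.full.aln.faa > {base}.aln.faa"
        )
    else:
        cmds.append(f"{cfg.aligner} {cfg.aligner_args} {base}.faa > {base}.aln.faa")
    cmds.append(
        f"bmge -i {base}.aln.faa -t AA -m {cfg.matrix} -h {cfg.entropy_threshold} "
        f"-b {cfg.min_length} -of {base}.trim.faa"
    )
    tree = (
        f"iqtree -s {base}.trim.faa"
        + (" -m MFP" if cfg.model_selection else "")
        + f" -alrt {cfg.sh_alrt_replicates}"
        + (" -abayes" if cfg.abayes else "")
        + f" -bb {cfg.ufboot_replicates} -seed {cfg.seed} -nt 1 -pre {base}"
    )
    cmds.append(tree)
    return cmds


def write_tool_manifest(commands: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("#!/bin/sh\nset -e\n" + "\n".join(commands) + "\n")
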
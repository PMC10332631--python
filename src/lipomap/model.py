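"""Core value types shared across the pipeline.

The pipeline moves genomes through four representations: raw profile-HMM
domain hits (:class:`DomainHit`), one functional label per protein
(:class:`FunctionalAnnotation`), strand-aware gene neighborhoods
(:class:`GeneCluster`), and per-genome presence/absence profiles
(:class:`GenomeProfile`).  Phylogenetic dataset construction adds
:class:`PhyloRecord`, a (possibly concatenated or rotated) amino-acid
sequence with partition bookkeeping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class Label(str, enum.Enum):
    """Functional labels assignable to a protein.

    ``LPL`` is the catalytic lipoate:protein ligase domain (any subtype --
    the profile HMMs cannot distinguish Lpl(AB), sLpl(AB), LplJ, etc., so
    every detected ligase is labelled Lpl and subtypes are resolved later
    from genomic context).  ``LPLB`` is the accessory ligase domain
    (Pfam PF10437).  ``LIPB``/``LIPM`` are octanoyltransferases, ``LIPA``
    the stand-alone lipoyl synthase, ``LIPS1``/``LIPS2`` the two-component
    lipoyl synthase pair, ``LIPT`` the FAD-binding oxidoreductase proposed
    to feed electrons to LipS1/S2, ``LIPL`` the amidotransferase.
    ``GCVH``/``LBPA``/``LD`` are lipoyl-domain acceptor proteins.
    ``SHDR`` marks the sulfur-oxidizing heterodisulfide-reductase-like
    system.  ``BIRA`` (biotin ligase) and ``BIOB`` (biotin synthase) are
    outgroup families for tree rooting.
    """

    LPL = "Lpl"
    LPLB = "LplB"
    LIPB = "LipB"
    LIPM = "LipM"
    LIPA = "LipA"
    LIPS1 = "LipS1"
    LIPS2 = "LipS2"
    LIPT = "LipT"
    LIPL = "LipL"
    GCVH = "GcvH"
    LBPA = "LbpA"
    LD = "LD"
    SHDR = "sHdr"
    BIRA = "BirA"
    BIOB = "BioB"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DomainOrder(str, enum.Enum):
    """Relative order of the catalytic (A) and accessory (B) ligase domains."""

    A_THEN_B = "A_then_B"
    B_THEN_A = "B_then_A"
    SINGLE = "single"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on a protein.

    Coordinates are 1-based inclusive envelope positions on the protein.
    ``trusted_cutoff`` is the model-curated bitscore threshold; hits at or
    above it are accepted (inclusive comparison, HMMER convention).
    """

    protein_id: str
    hmm_acc: str
    bitscore: float
    trusted_cutoff: float
    env_from: int
    env_to: int

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(
                f"envelope inverted for {self.protein_id}/{self.hmm_acc}: "
                f"{self.env_from} > {self.env_to}"
            )
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError(f"non-finite bitscore for {self.protein_id}/{self.hmm_acc}")

    @property
    def above_cutoff(self) -> bool:
        return self.bitscore >= self.trusted_cutoff

    @property
    def env_len(self) -> int:
        return self.env_to - self.env_from + 1

    @property
    def midpoint(self) -> float:
        return (self.env_from + self.env_to) / 2.0


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Per-protein enzyme label plus domain-architecture flags.

    ``label is Label.NONE`` iff ``best_hit is None``.  ``has_lplB_domain``
    is set only for ligases carrying an accepted accessory-domain
    (PF10437) hit whose envelope does not substantially overlap the
    catalytic envelope; ``domain_order`` then records which domain comes
    first on the chain (fused Lpl(AB) vs circularly permuted Lpl(BA)).
    """

    protein_id: str
    label: Label = Label.NONE
    best_hit: DomainHit | None = None
    has_lplB_domain: bool = False
    domain_order: DomainOrder = DomainOrder.NOT_APPLICABLE
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.label is Label.NONE) != (self.best_hit is None):
            raise ValueError(
                f"{self.protein_id}: label NONE must coincide with absent best_hit"
            )
        if self.domain_order in (DomainOrder.A_THEN_B, DomainOrder.B_THEN_A) and not (
            self.label is Label.LPL and self.has_lplB_domain
        ):
            raise ValueError(
                f"{self.protein_id}: two-domain order requires a fused ligase"
            )

    def with_architecture(
        self, has_lplB: bool, order: DomainOrder, extra_notes: tuple[str, ...] = ()
    ) -> "FunctionalAnnotation":
        return replace(
            self,
            has_lplB_domain=has_lplB,
            domain_order=order,
            notes=self.notes + extra_notes,
        )


@dataclass(frozen=True)
class GeneRecord:
    """One gene call on a contig; coordinates are 1-based inclusive (GFF3)."""

    genome_id: str
    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: strand must be '+' or '-'")


@dataclass
class GeneCluster:
    """Ordered, strand-aware run of co-localized annotated genes."""

    genome_id: str
    contig_id: str
    members: list[tuple[GeneRecord, FunctionalAnnotation]]

    def labels(self) -> list[Label]:
        return [ann.label for _, ann in self.members]

    def protein_ids(self) -> list[str]:
        return [g.protein_id for g, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


class LigaseSubtype(str, enum.Enum):
    CLASSICAL_LPL = "classical_Lpl"
    SLPL_AB = "sLpl_AB"
    BIPARTITE_LPLAB = "bipartite_LplAB"
    CPLPL_BA = "cpLpl_BA"
    LIPM_LIKE = "LipM_like"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class LigaseCall:
    """Context-based subtype call for one ligase protein."""

    protein_id: str
    subtype: LigaseSubtype
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subtype is not LigaseSubtype.UNDETERMINED and not self.rationale:
            raise ValueError(f"{self.protein_id}: determined subtype needs a rationale")


class PathwaySystem(str, enum.Enum):
    LIPB_LIPA = "LipB_LipA"
    LIPM_LIPA = "LipM_LipA"
    LPL_LIPA = "Lpl_LipA"
    SLPL_LIPS1S2 = "sLpl_LipS1S2"
    LPL_SCAVENGING_ONLY = "Lpl_scavenging_only"
    LIPM_LIPS1S2 = "LipM_LipS1S2"
    NONE = "none"


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    systems: frozenset[PathwaySystem]


# Presence/absence flag columns of the per-genome profile matrix, in the
# order they are written to TSV.
FLAG_NAMES: tuple[str, ...] = (
    "Lpl",
    "LipB",
    "LipM",
    "LipA",
    "LipS1",
    "LipS2",
    "LipS1S2",
    "LipT",
    "LipL",
    "sHdr",
    "LD",
)

# Labels folded into the single "LD" (lipoyl-domain acceptor) presence bit.
LD_LABELS = (Label.GCVH, Label.LBPA, Label.LD)

GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class GenomeProfile:
    """Per-genome presence/absence vector plus taxonomy.

    Copy counts per label are authoritative; presence flags derive from
    them (count > 0).  ``LipS1S2`` requires both synthase subunits, and
    ``LD`` pools all lipoyl-domain acceptor labels (GcvH, LbpA, generic
    E2 lipoyl domains) into one bit while individual counts stay
    available.
    """

    genome_id: str
    taxonomy: dict[str, str]
    counts: dict[Label, int] = field(default_factory=dict)

    @property
    def domain(self) -> str:
        return self.taxonomy.get("domain", "")

    @property
    def phylum(self) -> str:
        return self.taxonomy.get("phylum", "")

    def count(self, label: Label) -> int:
        return self.counts.get(label, 0)

    def flag(self, name: str) -> bool:
        if name == "LipS1S2":
            return self.flag("LipS1") and self.flag("LipS2")
        if name == "LD":
            return any(self.count(lab) > 0 for lab in LD_LABELS)
        return self.count(Label(name)) > 0

    def flags(self) -> dict[str, bool]:
        return {name: self.flag(name) for name in FLAG_NAMES}


class Provenance(str, enum.Enum):
    NATIVE = "native"
    CONCAT_SYNTENIC = "concat_syntenic"
    CP_NORMALIZED = "cp_normalized"
    CONCAT_LIPS1S2 = "concat_lipS1S2"
    OUTGROUP = "outgroup"


@dataclass(frozen=True)
class PhyloRecord:
    """A sequence destined for a named phylogenetic dataset.

    ``partitions`` are 1-based inclusive (name, start, end) segments that
    must tile the sequence without gaps or overlap; concatenated records
    carry one partition per source gene.
    """

    record_id: str
    sequence: str
    partitions: tuple[tuple[str, int, int], ...]
    provenance: Provenance = Provenance.NATIVE
    label: Label = Label.NONE

    def __post_init__(self) -> None:
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError(
                    f"{self.record_id}: partitions must tile [1, len] "
                    f"(segment {name} spans {start}-{end}, expected start {pos})"
                )
            pos = end + 1
        if pos - 1 != len(self.sequence):
            raise ValueError(
                f"{self.record_id}: partition span {pos - 1} != sequence length "
                f"{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)
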
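"""Synthetic-genome generator with ground truth, for pipeline testing.

Each generated genome carries a planted pathway type: an ordered gene
cluster (e.g. lipS1-lpl(AB)-lipT-lipS2, or the archaeal
lipS2-lplA-lplB-lipS1 arrangement), loose pathway genes, and decoy
genes.  Labels are realized as above-cutoff simulated HMM hits
(bitscore = trusted cutoff + positive margin); decoys receive
below-cutoff hits or none.  Fused ligases carry catalytic + accessory
envelope pairs in A-then-B or (circularly permuted) B-then-A order.
Protein sequences are random strings over the amino-acid alphabet with
label-specific length distributions -- hits are simulated, not
searched, which keeps the test suite independent of any HMM database.

Noise knobs (missing genes, paralog injection, contig splits) perturb
genomes away from their planted truth; the ground-truth manifest is
updated by simulate's own rule table, independent of the typing module
it is used to test.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import HmmCatalog
from .model import DomainHit, GeneRecord, Label

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Mean/sd of protein length per label; decoys draw uniform 100-500.
LABEL_LENGTHS: dict[str, tuple[int, int]] = {
    "Lpl_fused": (340, 15),
    "lplA": (240, 12),
    "lplB": (95, 8),
    "LipA": (300, 12),
    "LipB": (220, 12),
    "LipM": (270, 12),
    "LipS1": (320, 12),
    "LipS2": (330, 12),
    "LipT": (420, 15),
    "LipL": (290, 12),
    "GcvH": (130, 6),
    "LbpA": (140, 6),
    "LD": (110, 6),
    "sHdr": (350, 12),
    "BirA": (320, 12),
    "BioB": (330, 12),
}

# Arrangement-template tokens -> (annotation label, fused-ligase flag).
# "slpl(AB)" is accepted as an alias for a fused ligase planted in a
# sulfur-oxidizer context; annotation-level ground truth records it as
# the canonical fused-ligase token lpl(AB).
_TOKEN_LABEL: dict[str, tuple[Label, bool]] = {
    "lpl(AB)": (Label.LPL, True),
    "slpl(AB)": (Label.LPL, True),
    "lpl(BA)": (Label.LPL, True),
    "lplA": (Label.LPL, False),
    "lplB": (Label.LPLB, False),
    "lipA": (Label.LIPA, False),
    "lipB": (Label.LIPB, False),
    "lipM": (Label.LIPM, False),
    "lipS1": (Label.LIPS1, False),
    "lipS2": (Label.LIPS2, False),
    "lipT": (Label.LIPT, False),
    "lipL": (Label.LIPL, False),
    "gcvH": (Label.GCVH, False),
    "lbpA": (Label.LBPA, False),
    "ld": (Label.LD, False),
    "sHdr": (Label.SHDR, False),
    "birA": (Label.BIRA, False),
    "bioB": (Label.BIOB, False),
}

BACTERIAL_PHYLA = (
    "Proteobacteria", "Firmicutes", "Chloroflexota", "Thermotogota", "Synergistota",
    "Actinomycetota",
)
ARCHAEAL_PHYLA = ("Thermoproteota", "Halobacteriota", "Asgardarchaeota", "Methanobacteriota")


@dataclass(frozen=True)
class GenomeType:
    """Planted composition of one genome category."""

    name: str
    domain: str  # Bacteria | Archaea
    cluster: tuple[str, ...] = ()  # ordered arrangement template tokens
    loose: tuple[str, ...] = ()  # unclustered pathway genes
    mix_applies: bool = False  # fused/split/permuted mix applies to the cluster ligase


GENOME_TYPES: dict[str, GenomeType] = {
    t.name: t
    for t in (
        GenomeType("bac_lipB_lipA", "Bacteria", loose=("lipB", "lipA", "gcvH", "ld", "birA", "bioB")),
        GenomeType("bac_lipM_lipA", "Bacteria", loose=("lipM", "lipA", "lipL", "gcvH")),
        GenomeType("bac_lpl_lipA", "Bacteria", loose=("lpl(AB)", "lipA", "gcvH"), mix_applies=True),
        GenomeType(
            "bac_slpl_lipS1S2",
            "Bacteria",
            cluster=("lipS1", "slpl(AB)", "lipT", "lipS2"),
            loose=("gcvH",),
            mix_applies=True,
        ),
        GenomeType(
            "bac_slpl_lipS1S2_shdr",
            "Bacteria",
            cluster=("lipS1", "slpl(AB)", "lipT", "lipS2"),
            loose=("sHdr", "lbpA"),
            mix_applies=True,
        ),
        GenomeType(
            "bac_lipM_lipS1S2", "Bacteria", cluster=("lipS1", "lipM", "lipS2"), loose=("gcvH",)
        ),
        GenomeType("bac_scavenger", "Bacteria", loose=("lpl(AB)", "gcvH"), mix_applies=True),
        GenomeType("bac_none", "Bacteria", loose=("gcvH",)),
        GenomeType(
            "arc_lplAB_lipS1S2",
            "Archaea",
            cluster=("lipS2", "lplA", "lplB", "lipS1"),
            loose=("lipT",),
        ),
        GenomeType(
            "arc_slpl_lipS1S2_shdr",
            "Archaea",
            cluster=("lipS1", "slpl(AB)", "lipT", "lipS2"),
            loose=("sHdr", "lbpA"),
            mix_applies=True,
        ),
        GenomeType("arc_lpl_lipA", "Archaea", loose=("lpl(AB)", "lipA"), mix_applies=True),
        GenomeType("arc_scavenger", "Archaea", loose=("lplA", "birA", "bioB")),
        GenomeType("arc_none", "Archaea", loose=()),
    )
}

#: Cohort composition used as the package default: an uneven mixture of
#: pathway types across both prokaryotic domains, noise-free (complete
#: genomes), matching how every recovery property is stated.
DEFAULT_N_PER_TYPE: dict[str, int] = {
    "bac_lipB_lipA": 30,
    "bac_lipM_lipA": 20,
    "bac_lpl_lipA": 14,
    "bac_slpl_lipS1S2": 6,
    "bac_slpl_lipS1S2_shdr": 4,
    "bac_lipM_lipS1S2": 4,
    "bac_scavenger": 12,
    "bac_none": 10,
    "arc_lplAB_lipS1S2": 10,
    "arc_slpl_lipS1S2_shdr": 6,
    "arc_lpl_lipA": 4,
    "arc_scavenger": 16,
    "arc_none": 14,
}


@dataclass
class SimSpec:
    """Generator configuration: cohort composition, architecture mix, noise."""

    n_per_type: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_TYPE))
    architecture_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)  # fused:split:permuted
    missing_gene_p: float = 0.0
    paralog_p: float = 0.0
    contig_split_p: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.architecture_mix) - 1.0) > 1e-9:
            raise ValueError("architecture mix proportions must sum to 1")
        for p in (self.missing_gene_p, self.paralog_p, self.contig_split_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must lie in [0, 1]")
        for name in self.n_per_type:
            if name not in GENOME_TYPES:
                raise ValueError(f"unknown genome type {name!r}")
        fused, split, permuted = self.architecture_mix
        if permuted > 0 and not any(
            GENOME_TYPES[n].mix_applies and c > 0 for n, c in self.n_per_type.items()
        ):
            if permuted == 1.0:
                raise ValueError("permuted architectures requested but no ligase genomes")


@dataclass
class GenomeTruth:
    """Planted ground truth for one genome."""

    genome_id: str
    type_name: str
    domain: str
    phylum: str
    labels: dict[str, str]  # protein_id -> label value ("Lpl", ...)
    architectures: dict[str, str]  # protein_id -> single|A_then_B|B_then_A
    pathways: frozenset[str]
    ligase_subtype: str | None
    arrangement: str | None  # canonical annotation-token string, None if not guaranteed


@dataclass
class SimGenome:
    genome_id: str
    taxonomy: str
    genes: list[GeneRecord]
    sequences: dict[str, str]
    hits: list[DomainHit]
    truth: GenomeTruth


@dataclass
class Cohort:
    spec: SimSpec
    genomes: list[SimGenome]

    def truth_by_genome(self) -> dict[str, GenomeTruth]:
        return {g.genome_id: g.truth for g in self.genomes}


# ---------------------------------------------------------------------------
# Independent rule table for expected pathway systems (the oracle used to
# update ground truth after perturbations; intentionally NOT a call into
# the typing module under test).


def expected_pathways(label_counts: Mapping[str, int]) -> frozenset[str]:
    n = lambda k: label_counts.get(k, 0)  # noqa: E731
    lpl = n("Lpl") > 0
    lipa = n("LipA") > 0
    s12 = n("LipS1") > 0 and n("LipS2") > 0
    systems = set()
    if n("LipB") > 0 and lipa:
        systems.add("LipB_LipA")
    if n("LipM") > 0 and lipa:
        systems.add("LipM_LipA")
    if lpl and lipa:
        systems.add("Lpl_LipA")
    if lpl and s12:
        systems.add("sLpl_LipS1S2")
    if n("LipM") > 0 and s12 and not lpl:
        systems.add("LipM_LipS1S2")
    if lpl and not lipa and not s12:
        systems.add("Lpl_scavenging_only")
    return frozenset(systems) if systems else frozenset({"none"})


def _expected_subtype(
    architecture: str, split_pair: bool, in_s_cluster: bool, s12: bool, lipa: bool, n_ligases: int
) -> str:
    if architecture == "B_then_A":
        return "cpLpl_BA"
    if split_pair:
        return "bipartite_LplAB"
    if in_s_cluster or (s12 and n_ligases == 1):
        return "sLpl_AB"
    if lipa and not s12:
        return "classical_Lpl"
    return "undetermined"


# ---------------------------------------------------------------------------
# Generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _protein_length(rng: np.random.Generator, token: str, fused: bool) -> int:
    key = "Lpl_fused" if fused else {"lplA": "lplA", "lplB": "lplB"}.get(token)
    if key is None:
        label = _TOKEN_LABEL[token][0]
        key = label.value
    mean, sd = LABEL_LENGTHS.get(key, (250, 20))
    return max(60, int(round(rng.normal(mean, sd))))


def _model_acc(catalog: HmmCatalog, label: Label) -> str:
    accs = catalog.accessions_for(label)
    if not accs:
        raise ValueError(f"catalog has no model for label {label.value}")
    return accs[0]


def _hits_for_gene(
    rng: np.random.Generator,
    catalog: HmmCatalog,
    pid: str,
    token: str,
    fused: bool,
    architecture: str,
    length: int,
) -> list[DomainHit]:
    label = _TOKEN_LABEL[token][0]
    margin = float(rng.uniform(5.0, 120.0))
    if not fused:
        acc = _model_acc(catalog, label)
        cutoff = catalog.cutoff_of(acc)
        return [
            DomainHit(pid, acc, cutoff + margin, cutoff, 5, max(6, length - 5)),
        ]
    acc_a = _model_acc(catalog, Label.LPL)
    acc_b = _model_acc(catalog, Label.LPLB)
    cut_a, cut_b = catalog.cutoff_of(acc_a), catalog.cutoff_of(acc_b)
    len_b = min(95, length // 3)
    if architecture == "A_then_B":
        a_env = (8, length - len_b - 10)
        b_env = (length - len_b - 2, length - 3)
    else:  # B_then_A (circularly permuted)
        b_env = (4, len_b)
        a_env = (len_b + 12, length - 5)
    return [
        DomainHit(pid, acc_a, cut_a + margin, cut_a, a_env[0], a_env[1]),
        DomainHit(pid, acc_b, cut_b + float(rng.uniform(5.0, 60.0)), cut_b, b_env[0], b_env[1]),
    ]


@dataclass
class _PlannedGene:
    token: str | None  # None => decoy
    fused: bool = False
    architecture: str = "single"
    in_cluster: bool = False


def _plan_genome(
    rng: np.random.Generator, gtype: GenomeType, mix: tuple[float, float, float]
) -> tuple[list[_PlannedGene], str | None]:
    """Lay out the gene order and resolve the ligase architecture draw.

    Returns the ordered gene plan and the drawn architecture
    ("fused"/"split"/"permuted") when the mix applies, else None.
    """
    arch_draw: str | None = None
    cluster_tokens = list(gtype.cluster)
    loose_tokens = list(gtype.loose)

    def resolve(tokens: list[str]) -> list[tuple[str, bool, str]]:
        nonlocal arch_draw
        out = []
        for tok in tokens:
            lab, fused = _TOKEN_LABEL[tok]
            if fused and gtype.mix_applies:
                if arch_draw is None:
                    arch_draw = str(rng.choice(["fused", "split", "permuted"], p=list(mix)))
                if arch_draw == "split":
                    out.append(("lplA", False, "single"))
                    out.append(("lplB", False, "single"))
                    continue
                if arch_draw == "permuted":
                    out.append((tok, True, "B_then_A"))
                    continue
                out.append((tok, True, "A_then_B"))
            elif fused:
                out.append((tok, True, "A_then_B"))
            else:
                out.append((tok, False, "single"))
        return out

    cluster_resolved = resolve(cluster_tokens)
    loose_resolved = resolve(loose_tokens)

    plan: list[_PlannedGene] = []
    n_lead = int(rng.integers(2, 6))
    plan += [_PlannedGene(None) for _ in range(n_lead)]
    for tok, fused, arch in cluster_resolved:
        plan.append(_PlannedGene(tok, fused, arch, in_cluster=True))
    # Separate each loose labelled gene by > max_gap decoys so planted
    # clusters never absorb a stray neighbor.  A split bipartite ligase
    # resolves to consecutive lplA+lplB genes, which stay adjacent: the
    # two-gene form is encoded as a syntenic pair.
    prev_tok: str | None = None
    for tok, fused, arch in loose_resolved:
        if not (tok == "lplB" and prev_tok == "lplA"):
            plan += [_PlannedGene(None) for _ in range(5)]
        plan.append(_PlannedGene(tok, fused, arch))
        prev_tok = tok
    plan += [_PlannedGene(None) for _ in range(int(rng.integers(3, 7)))]
    return plan, arch_draw


# Canonical annotation-level arrangement token for a planted gene.
def _truth_token(token: str, fused: bool, architecture: str) -> str:
    if fused:
        return "lpl(AB)" if architecture == "A_then_B" else "lpl(BA)"
    if token == "slpl(AB)":
        return "lpl(AB)"
    if token == "sHdr":
        return "sHdr"
    return token


def generate(spec: SimSpec, catalog: HmmCatalog | None = None) -> Cohort:
    """Generate a cohort of synthetic genomes with ground truth.

    Deterministic for a fixed spec and seed: two calls produce identical
    objects and byte-identical files.
    """
    spec.validate()
    catalog = catalog or HmmCatalog.default()
    rng = np.random.default_rng(spec.seed)
    genomes: list[SimGenome] = []
    gidx = 0
    for type_name in sorted(spec.n_per_type):
        gtype = GENOME_TYPES[type_name]
        phyla = BACTERIAL_PHYLA if gtype.domain == "Bacteria" else ARCHAEAL_PHYLA
        for i in range(spec.n_per_type[type_name]):
            gidx += 1
            gid = f"SIM{gidx:04d}"
            phylum = phyla[i % len(phyla)]
            genomes.append(_generate_genome(rng, spec, catalog, gtype, gid, phylum))
    return Cohort(spec=spec, genomes=genomes)


def _generate_genome(
    rng: np.random.Generator,
    spec: SimSpec,
    catalog: HmmCatalog,
    gtype: GenomeType,
    gid: str,
    phylum: str,
) -> SimGenome:
    plan, _ = _plan_genome(rng, gtype, spec.architecture_mix)

    # Missing-gene noise: drop planted genes independently.
    kept_plan: list[_PlannedGene] = []
    dropped_any_cluster = False
    for pg in plan:
        if pg.token is not None and spec.missing_gene_p > 0 and rng.random() < spec.missing_gene_p:
            if pg.in_cluster:
                dropped_any_cluster = True
            continue
        kept_plan.append(pg)

    # Paralog injection: duplicate one random planted gene at the contig end.
    if spec.paralog_p > 0 and rng.random() < spec.paralog_p:
        labelled = [pg for pg in kept_plan if pg.token is not None]
        if labelled:
            src = labelled[int(rng.integers(0, len(labelled)))]
            kept_plan += [_PlannedGene(None) for _ in range(5)]
            kept_plan.append(_PlannedGene(src.token, src.fused, src.architecture))

    # Contig split: cut the gene order at a random boundary.
    split_at: int | None = None
    if spec.contig_split_p > 0 and rng.random() < spec.contig_split_p and len(kept_plan) > 2:
        split_at = int(rng.integers(1, len(kept_plan)))

    genes: list[GeneRecord] = []
    sequences: dict[str, str] = {}
    hits: list[DomainHit] = []
    labels: dict[str, str] = {}
    architectures: dict[str, str] = {}
    cluster_strand = "+" if rng.random() < 0.5 else "-"
    split_inside_cluster = False

    # Truth arrangement tokens follow the template reading order; on the
    # minus strand the genes are laid on the contig in reverse order so
    # that reading along the coding strand reproduces the template.
    cluster_truth_tokens = [
        _truth_token(pg.token, pg.fused, pg.architecture)
        for pg in kept_plan
        if pg.in_cluster and pg.token is not None
    ]
    if cluster_strand == "-":
        idxs = [i for i, pg in enumerate(kept_plan) if pg.in_cluster]
        if idxs:
            block = [kept_plan[i] for i in idxs][::-1]
            for i, pg in zip(idxs, block):
                kept_plan[i] = pg

    pos = int(rng.integers(100, 500))
    pidx = 0
    gene_index = 0
    contig_no = 1
    prev_in_cluster = False
    for i, pg in enumerate(kept_plan):
        if split_at is not None and i == split_at:
            contig_no = 2
            gene_index = 0
            pos = int(rng.integers(100, 500))
            if prev_in_cluster and i < len(kept_plan) and any(
                p.in_cluster for p in kept_plan[i:]
            ):
                split_inside_cluster = True
        pidx += 1
        pid = f"{gid}_p{pidx:04d}"
        if pg.token is None:
            length = int(rng.integers(100, 501))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _random_seq(rng, length)
            # a third of decoys get a below-cutoff hit on a random model
            if rng.random() < 0.33:
                entry = catalog.entries[int(rng.integers(0, len(catalog)))]
                hits.append(
                    DomainHit(
                        pid,
                        entry.acc,
                        entry.trusted_cutoff - float(rng.uniform(5.0, 50.0)),
                        entry.trusted_cutoff,
                        5,
                        max(6, length - 5),
                    )
                )
        else:
            length = _protein_length(rng, pg.token, pg.fused)
            strand = cluster_strand if pg.in_cluster else ("+" if rng.random() < 0.5 else "-")
            seq = _random_seq(rng, length)
            hits.extend(
                _hits_for_gene(rng, catalog, pid, pg.token, pg.fused, pg.architecture, length)
            )
            label = _TOKEN_LABEL[pg.token][0]
            labels[pid] = label.value
            architectures[pid] = pg.architecture if pg.fused else "single"
        start = pos
        end = pos + 3 * length + 2
        pos = end + int(rng.integers(20, 200))
        genes.append(
            GeneRecord(
                genome_id=gid,
                contig_id=f"{gid}_c{contig_no}",
                gene_index=gene_index,
                start=start,
                end=end,
                strand=strand,
                protein_id=pid,
            )
        )
        gene_index += 1
        sequences[pid] = seq
        prev_in_cluster = pg.in_cluster

    label_counts = Counter(labels.values())
    pathways = expected_pathways(label_counts)

    # Ligase subtype truth (only when exactly one ligase survives).
    subtype: str | None = None
    lig_pids = [p for p, lab in labels.items() if lab == "Lpl"]
    if lig_pids:
        n_lig = len(lig_pids)
        pid0 = sorted(lig_pids)[0]
        arch = architectures[pid0]
        in_cluster_plan = [
            pg for pg in kept_plan if pg.token is not None and _TOKEN_LABEL[pg.token][0] is Label.LPL
        ]
        in_s_cluster = any(
            pg.in_cluster for pg in in_cluster_plan
        ) and any(t in ("lipS1", "lipS2") for t in cluster_truth_tokens)
        split_pair = (
            arch == "single"
            and "LplB" in label_counts
            and not split_inside_cluster
        )
        if arch == "single" and split_pair:
            arch_for_rule = "single"
        else:
            arch_for_rule = arch
        s12 = label_counts.get("LipS1", 0) > 0 and label_counts.get("LipS2", 0) > 0
        subtype = _expected_subtype(
            arch_for_rule,
            split_pair,
            in_s_cluster and not split_inside_cluster,
            s12,
            label_counts.get("LipA", 0) > 0,
            n_lig,
        )

    arrangement: str | None = None
    if gtype.cluster and not dropped_any_cluster and not split_inside_cluster:
        arrangement = "-".join(cluster_truth_tokens)

    dom_prefixes = {
        "Bacteria": ("Bacteria", "Gammaproteobacteria"),
        "Archaea": ("Archaea", "Thermococci"),
    }
    dom, clazz = dom_prefixes[gtype.domain]
    taxonomy = (
        f"d__{dom};p__{phylum};c__{clazz};o__o{phylum[:4]};"
        f"f__f{phylum[:4]};g__g{gid};s__g{gid} sp{gid[3:]}"
    )
    truth = GenomeTruth(
        genome_id=gid,
        type_name=gtype.name,
        domain=gtype.domain,
        phylum=phylum,
        labels=labels,
        architectures=architectures,
        pathways=pathways,
        ligase_subtype=subtype,
        arrangement=arrangement,
    )
    hits.sort(key=lambda h: (h.protein_id, h.hmm_acc, h.env_from))
    return SimGenome(gid, taxonomy, genes, sequences, hits, truth)


# ---------------------------------------------------------------------------
# Perturbations


def perturb(genome: SimGenome, operation: str, target: str, seed: int = 0) -> SimGenome:
    """Apply one named perturbation; ground truth is updated by rule.

    ``operation`` is drop_gene / duplicate_gene / split_contig.
    ``target`` names a protein_id (or, for drop/duplicate, a label value
    such as "LipS2" -- the first matching gene is used; for
    split_contig, the split happens immediately before the target
    gene).  Raises KeyError on unknown genes.
    """
    rng = np.random.default_rng(seed)

    def find_pid(t: str) -> str:
        if t in genome.sequences:
            return t
        for pid in sorted(genome.truth.labels):
            if genome.truth.labels[pid] == t:
                return pid
        raise KeyError(f"no gene matching {t!r} in {genome.genome_id}")

    pid = find_pid(target)
    genes = list(genome.genes)
    sequences = dict(genome.sequences)
    hits = list(genome.hits)
    labels = dict(genome.truth.labels)
    architectures = dict(genome.truth.architectures)
    arrangement = genome.truth.arrangement
    subtype = genome.truth.ligase_subtype

    cluster_pids = _cluster_pids(genome)

    if operation == "drop_gene":
        genes = [g for g in genes if g.protein_id != pid]
        sequences.pop(pid)
        hits = [h for h in hits if h.protein_id != pid]
        dropped_label = labels.pop(pid, None)
        architectures.pop(pid, None)
        if pid in cluster_pids:
            arrangement = None
        if dropped_label == "Lpl":
            subtype = None
    elif operation == "duplicate_gene":
        new_pid = f"{pid}_dup"
        last = max(genes, key=lambda g: (g.contig_id, g.gene_index))
        genes.append(
            GeneRecord(
                genome_id=genome.genome_id,
                contig_id=last.contig_id,
                gene_index=last.gene_index + 6,
                start=last.end + 5000,
                end=last.end + 5000 + (len(sequences[pid]) * 3 + 2),
                strand="+",
                protein_id=new_pid,
            )
        )
        sequences[new_pid] = sequences[pid]
        for h in [h for h in hits if h.protein_id == pid]:
            hits.append(replace(h, protein_id=new_pid))
        if pid in labels:
            labels[new_pid] = labels[pid]
            architectures[new_pid] = architectures.get(pid, "single")
    elif operation == "split_contig":
        target_gene = next(g for g in genes if g.protein_id == pid)
        old_contig = target_gene.contig_id
        new_contig = old_contig + "s"
        out = []
        moved = set()
        for g in sorted(genes, key=lambda g: (g.contig_id, g.gene_index)):
            if g.contig_id == old_contig and g.gene_index >= target_gene.gene_index:
                out.append(
                    replace(
                        g,
                        contig_id=new_contig,
                        gene_index=g.gene_index - target_gene.gene_index,
                    )
                )
                moved.add(g.protein_id)
            else:
                out.append(g)
        genes = out
        if cluster_pids and (cluster_pids & moved) and (cluster_pids - moved):
            arrangement = None
            if subtype in ("sLpl_AB", "bipartite_LplAB"):
                subtype = None
    else:
        raise ValueError(f"unknown perturbation {operation!r}")

    pathways = expected_pathways(Counter(labels.values()))
    truth = GenomeTruth(
        genome_id=genome.genome_id,
        type_name=genome.truth.type_name,
        domain=genome.truth.domain,
        phylum=genome.truth.phylum,
        labels=labels,
        architectures=architectures,
        pathways=pathways,
        ligase_subtype=subtype,
        arrangement=arrangement,
    )
    del rng  # reserved for future randomized perturbations
    return SimGenome(genome.genome_id, genome.taxonomy, genes, sequences, hits, truth)


def _cluster_pids(genome: SimGenome) -> set[str]:
    gtype = GENOME_TYPES[genome.truth.type_name]
    if not gtype.cluster:
        return set()
    wanted = Counter(_TOKEN_LABEL[t][0].value for t in gtype.cluster)
    out = set()
    for pid in sorted(genome.truth.labels):
        lab = genome.truth.labels[pid]
        if wanted.get(lab, 0) > 0:
            out.add(pid)
            wanted[lab] -= 1
    return out


# ---------------------------------------------------------------------------
# File output (standard text formats + ground-truth JSON)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write proteins.faa, genes.gff3, hits.domtbl, taxonomy.tsv, ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "faa": outdir / "proteins.faa",
        "gff": outdir / "genes.gff3",
        "domtbl": outdir / "hits.domtbl",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "ground_truth.json",
    }

    with open(paths["faa"], "w") as fh:
        for g in cohort.genomes:
            for pid in sorted(g.sequences):
                seq = g.sequences[pid]
                fh.write(f">{pid} genome={g.genome_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in cohort.genomes:
            for gene in sorted(g.genes, key=lambda x: (x.contig_id, x.gene_index)):
                fh.write(
                    f"{gene.contig_id}\tlipomap_sim\tCDS\t{gene.start}\t{gene.end}\t.\t"
                    f"{gene.strand}\t0\tID={gene.protein_id};genome={gene.genome_id}\n"
                )

    write_domtblout(
        [h for g in cohort.genomes for h in g.hits],
        {pid: len(seq) for g in cohort.genomes for pid, seq in g.sequences.items()},
        paths["domtbl"],
    )

    with open(paths["taxonomy"], "w") as fh:
        fh.write("accession\tgtdb_taxonomy\tgtdb_representative\n")
        for g in cohort.genomes:
            fh.write(f"{g.genome_id}\t{g.taxonomy}\tt\n")

    truth_doc = {
        g.genome_id: {
            "type": g.truth.type_name,
            "domain": g.truth.domain,
            "phylum": g.truth.phylum,
            "labels": g.truth.labels,
            "architectures": g.truth.architectures,
            "pathways": sorted(g.truth.pathways),
            "ligase_subtype": g.truth.ligase_subtype,
            "arrangement": g.truth.arrangement,
        }
        for g in cohort.genomes
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True) + "\n")
    return paths


def write_domtblout(
    hits: Sequence[DomainHit], protein_lengths: Mapping[str, int], path: str | Path
) -> None:
    """Write hits in the hmmsearch ``--domtblout`` dialect (grouped by model)."""
    by_acc: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_acc.setdefault(h.hmm_acc, []).append(h)
    lines = [
        "#                                                               --- full sequence --- "
        "-------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  "
        "score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    "
        "to  acc description of target",
    ]
    for acc in sorted(by_acc):
        per_protein: dict[str, list[DomainHit]] = {}
        for h in by_acc[acc]:
            per_protein.setdefault(h.protein_id, []).append(h)
        for pid in sorted(per_protein):
            doms = sorted(per_protein[pid], key=lambda h: h.env_from)
            full_score = sum(d.bitscore for d in doms)
            evalue = 10.0 ** (-full_score / 10.0)
            for i, d in enumerate(doms, start=1):
                tlen = protein_lengths.get(pid, d.env_to)
                dom_e = 10.0 ** (-d.bitscore / 10.0)
                lines.append(
                    f"{pid:<20s} {'-':<11s} {tlen:>5d} {acc:<20s} {acc:<11s} {max(d.env_len, 10):>6d} "
                    f"{evalue:9.2g} {full_score:6.1f} {0.0:5.1f} {i:>3d} {len(doms):>3d} "
                    f"{dom_e:9.2g} {dom_e:9.2g} {d.bitscore:6.1f} {0.0:5.1f} "
                    f"{1:>5d} {max(d.env_len, 10):>5d} {d.env_from:>5d} {d.env_to:>5d} "
                    f"{d.env_from:>5d} {d.env_to:>5d} 0.90 simulated"
                )
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n")
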
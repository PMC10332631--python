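"""Functional annotation of proteins from profile-HMM domain hits.

One label per protein: among all hits at or above their trusted cutoffs,
the model with the highest bitscore wins (ties resolved by catalog
priority, then lexicographic accession).  Ligases are additionally
screened for the accessory LplB domain (PF10437) to distinguish fused
Lpl(AB), circularly permuted Lpl(BA), and single-domain architectures.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO

from .catalog import HmmCatalog
from .model import DomainHit, DomainOrder, FunctionalAnnotation, Label

logger = logging.getLogger(__name__)

#: A two-domain architecture call requires the accessory envelope to
#: overlap the catalytic envelope by no more than this fraction of the
#: shorter envelope (fused domains abut, but envelopes may fray).
OVERLAP_TOLERANCE = 0.5


def filter_above_cutoff(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Keep exactly the hits with bitscore >= trusted cutoff (inclusive), order preserved."""
    return [h for h in hits if h.above_cutoff]


def _selection_key(hit: DomainHit, catalog: HmmCatalog):
    # Total order: best bitscore first, then catalog priority (low wins),
    # then accession, then envelope coordinates for full determinism.
    return (-hit.bitscore, catalog.priority_of(hit.hmm_acc), hit.hmm_acc, hit.env_from, hit.env_to)


def select_best_hit(hits: Sequence[DomainHit], catalog: HmmCatalog) -> FunctionalAnnotation:
    """Label a protein by its best above-cutoff hit.

    Hits on accessions absent from the catalog are ignored with a logged
    warning.  Returns a NONE annotation when nothing passes.  All hits
    must share one protein_id.
    """
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    known = []
    for h in hits:
        if h.hmm_acc in catalog:
            known.append(h)
        else:
            logger.warning("ignoring hit on unknown HMM accession %s (%s)", h.hmm_acc, h.protein_id)
    passing = filter_above_cutoff(known)
    if not passing:
        pid = next(iter(ids)) if ids else ""
        return FunctionalAnnotation(protein_id=pid)
    ranked = sorted(passing, key=lambda h: _selection_key(h, catalog))
    best = ranked[0]
    notes: tuple[str, ...] = ()
    if len(ranked) > 1:
        runner = ranked[1]
        if (
            runner.bitscore == best.bitscore
            and catalog.label_of(runner.hmm_acc) is not catalog.label_of(best.hmm_acc)
        ):
            # e.g. a protein scoring equally against ligase and
            # octanoyltransferase models: resolved deterministically but
            # flagged for review.
            notes = (f"ambiguous_tie:{catalog.label_of(runner.hmm_acc).value}",)
    return FunctionalAnnotation(
        protein_id=best.protein_id,
        label=catalog.label_of(best.hmm_acc),
        best_hit=best,
        notes=notes,
    )


def _envelope_overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.env_to, b.env_to) - max(a.env_from, b.env_from) + 1)


def detect_architecture(
    annotation: FunctionalAnnotation,
    hits: Sequence[DomainHit],
    catalog: HmmCatalog,
) -> FunctionalAnnotation:
    """Resolve the domain architecture of a ligase from its accessory-domain hits.

    For Lpl-labelled proteins, an above-cutoff PF10437 (LplB) hit on the
    same protein whose envelope does not overlap the catalytic envelope
    by more than half of the shorter envelope marks a fused two-domain
    ligase; envelope midpoints decide whether the catalytic domain comes
    first (Lpl(AB)) or last (circularly permuted Lpl(BA)).  Non-ligase
    annotations pass through unchanged.
    """
    if annotation.label is not Label.LPL or annotation.best_hit is None:
        return annotation
    catalytic = annotation.best_hit
    lplb_accs = set(catalog.accessions_for(Label.LPLB))
    candidates = [
        h
        for h in filter_above_cutoff(list(hits))
        if h.hmm_acc in lplb_accs and h.protein_id == annotation.protein_id
    ]
    if not candidates:
        return annotation.with_architecture(False, DomainOrder.SINGLE)
    # Best accessory hit by score, deterministic tie-break.
    candidates.sort(key=lambda h: (-h.bitscore, h.env_from, h.env_to))
    acc_hit = candidates[0]
    overlap = _envelope_overlap(catalytic, acc_hit)
    shorter = min(catalytic.env_len, acc_hit.env_len)
    if overlap > OVERLAP_TOLERANCE * shorter:
        logger.warning(
            "%s: accessory envelope overlaps catalytic envelope beyond tolerance "
            "(%d of %d residues); not calling a fused architecture",
            annotation.protein_id,
            overlap,
            shorter,
        )
        return annotation.with_architecture(False, DomainOrder.SINGLE, ("accessory_overlap",))
    order = (
        DomainOrder.A_THEN_B
        if catalytic.midpoint <= acc_hit.midpoint
        else DomainOrder.B_THEN_A
    )
    return annotation.with_architecture(True, order)


def annotate_proteome(
    protein_ids: Iterable[str],
    hits: Iterable[DomainHit],
    catalog: HmmCatalog,
) -> dict[str, FunctionalAnnotation]:
    """Annotate every protein of a proteome; deterministic and order-independent.

    Raises on hits that reference proteins absent from the protein set.
    """
    protein_ids = list(protein_ids)
    known = set(protein_ids)
    by_protein: dict[str, list[DomainHit]] = {pid: [] for pid in protein_ids}
    for h in hits:
        if h.protein_id not in known:
            raise KeyError(f"hit references unknown protein '{h.protein_id}'")
        by_protein[h.protein_id].append(h)
    out: dict[str, FunctionalAnnotation] = {}
    for pid in protein_ids:
        phits = sorted(
            by_protein[pid],
            key=lambda h: (h.hmm_acc, h.env_from, h.env_to, -h.bitscore),
        )
        ann = select_best_hit(phits, catalog) if phits else FunctionalAnnotation(protein_id=pid)
        out[pid] = detect_architecture(ann, phits, catalog)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta_ids(path: str | Path) -> list[str]:
    """Protein IDs (first token of each header) from a protein FASTA."""
    return [rec.id for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_domtblout(path: str | Path, catalog: HmmCatalog) -> list[DomainHit]:
    """Parse an hmmsearch ``--domtblout`` table into DomainHits.

    The text table does not carry the model's curated thresholds, so the
    trusted cutoff is taken from the catalog; hits on accessions the
    catalog does not know are dropped with a warning (they cannot be
    scored against any cutoff).
    """
    hits: list[DomainHit] = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        acc = qresult.accession if qresult.accession not in (None, "", "-") else qresult.id
        if acc not in catalog:
            logger.warning("domtblout: skipping unknown HMM accession %s", acc)
            continue
        cutoff = catalog.cutoff_of(acc)
        for hit in qresult.hits:
            for hsp in hit.hsps:
                hits.append(
                    DomainHit(
                        protein_id=hit.id,
                        hmm_acc=acc,
                        bitscore=float(hsp.bitscore),
                        trusted_cutoff=cutoff,
                        env_from=int(hsp.env_start) + 1,
                        env_to=int(hsp.env_end),
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.hmm_acc, h.env_from, h.env_to))
    return hits


def annotations_to_frame(annotations: Mapping[str, FunctionalAnnotation]) -> pd.DataFrame:
    rows = []
    for pid in sorted(annotations):
        a = annotations[pid]
        rows.append(
            {
                "protein_id": pid,
                "label": a.label.value,
                "hmm_acc": a.best_hit.hmm_acc if a.best_hit else "",
                "bitscore": a.best_hit.bitscore if a.best_hit else float("nan"),
                "has_lplB_domain": int(a.has_lplB_domain),
                "domain_order": a.domain_order.value,
                "notes": ";".join(a.notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "label",
            "hmm_acc",
            "bitscore",
            "has_lplB_domain",
            "domain_order",
            "notes",
        ],
    )


def write_annotations_tsv(annotations: Mapping[str, FunctionalAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str | Path) -> dict[str, FunctionalAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, FunctionalAnnotation] = {}
    for row in df.itertuples(index=False):
        label = Label(row.label)
        best = None
        if label is not Label.NONE:
            # Envelope coordinates are not round-tripped through the TSV;
            # a 1-residue stub keeps the hit's identity and score.
            best = DomainHit(
                protein_id=row.protein_id,
                hmm_acc=row.hmm_acc,
                bitscore=float(row.bitscore),
                trusted_cutoff=float("-1e9"),
                env_from=1,
                env_to=1,
            )
        out[row.protein_id] = FunctionalAnnotation(
            protein_id=row.protein_id,
            label=label,
            best_hit=best,
            has_lplB_domain=bool(int(row.has_lplB_domain)),
            domain_order=DomainOrder(row.domain_order),
            notes=tuple(str(row.notes).split(";")) if row.notes else (),
        )
    return out


def run_hmmsearch(
    faa_path: str | Path, hmm_path: str | Path, catalog: HmmCatalog
) -> list[DomainHit]:
    """Optional search backend: run profile HMMs against a proteome in-process.

    Requires ``pyhmmer`` and a pressed/loadable HMM file whose model
    accessions appear in the catalog.  Precomputed domtblout tables are
    the primary input path; this exists for end-to-end runs from raw
    proteomes.
    """
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    with pyhmmer.easel.SequenceFile(str(faa_path), digital=True, alphabet=alphabet) as sf:
        proteins = sf.read_block()
    hits: list[DomainHit] = []
    with pyhmmer.plan7.HMMFile(str(hmm_path)) as hf:
        for tophits in pyhmmer.hmmsearch(hf, proteins):
            acc = (tophits.query.accession or tophits.query.name or b"").decode()
            if acc not in catalog:
                logger.warning("hmmsearch: skipping unknown HMM accession %s", acc)
                continue
            cutoff = catalog.cutoff_of(acc)
            for hit in tophits:
                for dom in hit.domains:
                    hits.append(
                        DomainHit(
                            protein_id=hit.name.decode(),
                            hmm_acc=acc,
                            bitscore=float(dom.score),
                            trusted_cutoff=cutoff,
                            env_from=int(dom.env_from),
                            env_to=int(dom.env_to),
                        )
                    )
    hits.sort(key=lambda h: (h.protein_id, h.hmm_acc, h.env_from, h.env_to))
    return hits
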
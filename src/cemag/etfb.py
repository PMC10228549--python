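"""EtfB homolog identification and function differentiation.

The beta subunit of the electron transfer flavoprotein (EtfB) partners
either with electron-confurcating lactate dehydrogenase (ecLDH, lactic
acid utilization) or with the electron-bifurcating acyl-CoA dehydrogenase
(ACD, chain elongation).  Candidate EtfB loci are found with the translated
homology search against labeled reference proteins; each candidate is then
assigned to the nearest reference label by end-gap-free global-alignment
identity distance (1 - identity), with a minimum margin between the two
label groups required for a confident call — candidates without a clear
margin are labeled "other", mirroring homologs a phylogeny cannot place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .homology import SearchParams, search_genome, six_frame_translate
from .records import GenomeRecord

LABELS = ("LAU_associated", "ACD_associated")


@dataclass(frozen=True)
class EtfBReference:
    ref_id: str
    sequence: str
    label: str  # LAU_associated | ACD_associated

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass
class EtfBCandidate:
    genome_id: str
    contig_id: str
    frame: int
    sstart: int
    send: int
    protein: str  # translated candidate sequence
    aln_length: int


@dataclass
class EtfBCall:
    genome_id: str
    contig_id: str
    sstart: int
    send: int
    label: str  # LAU_associated | ACD_associated | other
    margin: float  # distance gap between best and second-best label


def read_references(path) -> list[EtfBReference]:
    """Reference FASTA with labels in headers: ``>id|LAU_associated``."""
    from .io import read_fasta

    refs = []
    for header, seq in read_fasta(path).items():
        if "|" not in header:
            raise ValueError(f"reference header {header!r} lacks '|label' suffix")
        rid, label = header.rsplit("|", 1)
        refs.append(EtfBReference(rid, seq, label))
    return refs


def find_etfb_homologs(
    genome: GenomeRecord,
    references: list[EtfBReference],
    params: SearchParams | None = None,
) -> list[EtfBCandidate]:
    """Candidate EtfB loci: translated-search hits of any reference, with
    overlapping hits on the same locus merged (longest alignment wins)."""
    params = params or SearchParams()
    queries = {f"{r.ref_id}|{r.label}": r.sequence for r in references}
    # keep every reference's best hit, then merge overlapping loci
    hits = []
    for name, seq in queries.items():
        hits.extend(search_genome({name: seq}, genome, params))
    hits.sort(key=lambda h: (h.contig_id, -(h.qend - h.qstart), h.sstart))
    merged: list = []
    for h in hits:
        overlaps = False
        for kept in merged:
            if kept.contig_id == h.contig_id and not (
                h.send < kept.sstart or h.sstart > kept.send
            ):
                overlaps = True
                break
        if not overlaps:
            merged.append(h)
    candidates = []
    for h in sorted(merged, key=lambda h: (h.contig_id, h.sstart)):
        frames = six_frame_translate(genome.contigs[h.contig_id])
        contig_len = len(genome.contigs[h.contig_id])
        # recover aa coordinates in the frame from forward-strand nt coords
        off = abs(h.frame) - 1
        if h.frame > 0:
            aa_start = (h.sstart - 1 - off) // 3
            aa_end = (h.send - off) // 3
        else:
            aa_start = (contig_len - h.send - off) // 3
            aa_end = (contig_len - h.sstart + 1 - off) // 3
        protein = frames[h.frame][aa_start:aa_end]
        candidates.append(EtfBCandidate(
            genome_id=genome.genome_id, contig_id=h.contig_id, frame=h.frame,
            sstart=h.sstart, send=h.send, protein=protein,
            aln_length=h.qend - h.qstart + 1,
        ))
    return candidates


def _global_identity(a: str, b: str) -> float:
    """End-gap-free global alignment identity: identical aligned pairs over
    the length of the shorter sequence.  Normalizing by length (rather than
    by aligned columns) keeps unrelated pairs distant even when the
    alignment covers only a short well-matching block."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    try:  # end gaps are free (end-gap-free global alignment)
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    aln = aligner.align(a.replace("*", "X"), b.replace("*", "X"))[0]
    matches = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        sa, sb = a[t0:t1], b[q0:q1]
        matches += sum(1 for x, y in zip(sa, sb) if x == y)
    shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0
    return matches / shorter


def assign_label(
    candidate: str,
    references: list[EtfBReference],
    margin_min: float = 0.10,
) -> tuple[str, float]:
    """Nearest-labeled-reference assignment with a confidence margin.

    Distance to each reference is 1 - global-alignment identity.  The
    candidate takes the nearest reference's label only when the best
    distance of the *other* label exceeds it by at least ``margin_min``;
    otherwise "other".  Returns (label, margin).
    """
    if not references:
        raise ValueError("empty reference set")
    best: dict[str, float] = {}
    for r in references:
        d = 1.0 - _global_identity(candidate, r.sequence)
        best[r.label] = min(best.get(r.label, np.inf), d)
    if len(best) < 2:
        only = next(iter(best))
        return only, float(np.inf)
    ordered = sorted(best.items(), key=lambda kv: kv[1])
    margin = ordered[1][1] - ordered[0][1]
    label = ordered[0][0] if margin >= margin_min else "other"
    return label, float(margin)


def call_genome_etfb(
    genome: GenomeRecord,
    references: list[EtfBReference],
    params: SearchParams | None = None,
    margin_min: float = 0.10,
) -> list[EtfBCall]:
    calls = []
    for cand in find_etfb_homologs(genome, references, params):
        label, margin = assign_label(cand.protein, references, margin_min)
        calls.append(EtfBCall(
            genome_id=cand.genome_id, contig_id=cand.contig_id,
            sstart=cand.sstart, send=cand.send, label=label,
            margin=float(min(margin, 9.99)),
        ))
    return calls


def summarize_etfb(
    calls: list[EtfBCall],
    functional_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genome booleans (has LAU-EtfB / ACD-EtfB / other) with the
    genome's functional group, plus a ``both`` flag for genomes carrying
    one homolog of each partnered type."""
    if not calls:
        return pd.DataFrame(columns=[
            "genome_id", "functional_group", "has_LAU_etfb", "has_ACD_etfb",
            "has_other_etfb", "has_both",
        ])
    rows = {}
    for c in calls:
        r = rows.setdefault(c.genome_id, {"LAU_associated": 0, "ACD_associated": 0, "other": 0})
        r[c.label] += 1
    out = []
    for gid in sorted(rows):
        r = rows[gid]
        out.append({
            "genome_id": gid,
            "functional_group": (functional_groups or {}).get(gid, ""),
            "has_LAU_etfb": int(r["LAU_associated"] > 0),
            "has_ACD_etfb": int(r["ACD_associated"] > 0),
            "has_other_etfb": int(r["other"] > 0),
            "has_both": int(r["LAU_associated"] > 0 and r["ACD_associated"] > 0),
        })
    return pd.DataFrame(out)


def calls_to_frame(calls: list[EtfBCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {"genome_id": c.genome_id, "contig_id": c.contig_id, "sstart": c.sstart,
         "send": c.send, "label": c.label, "margin": round(c.margin, 4)}
        for c in calls
    ])
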
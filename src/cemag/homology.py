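"""Translated protein homology search (tBLASTn-style).

Each protein query is aligned against all six reading frames of every
contig with an affine-gap local (Smith–Waterman) aligner scored by a
standard substitution matrix (BLOSUM62 by default, gap open 11 / extend 1).
Significance follows the Karlin–Altschul convention,

    bitscore = (lambda * raw_score - ln K) / ln 2
    E        = m * n * 2**(-bitscore)

with the gapped BLOSUM62 constants lambda = 0.267, K = 0.041 and an
uncorrected m*n search space.  Hits are filtered on E-value, percent
identity ("pident") and query coverage ("qcovhsp"), and at most one hit —
the best-scoring — is retained per (query, genome), since downstream
analyses consume presence/absence only.

The aligner itself is exact: a row-vectorized Gotoh dynamic program whose
horizontal-gap state is resolved with a prefix-max scan, so the best score
always equals the full affine-gap Smith–Waterman optimum.  On large frames
``search_genome`` first screens for candidate regions with exact k-mer word
seeding (two word hits in a diagonal band required, as in BLAST's two-hit
heuristic) and then runs the exact aligner on a diagonal band around the
seeds; frames small enough to align exhaustively are aligned exhaustively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .records import GenomeRecord, PathwayCatalog

_NEG = np.int32(-(10**8))

# Protein alphabet used for encoding; includes ambiguity 'X' and stop '*'.
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_AA)}


def _load_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    n = len(_AA)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            aa = a if a in mat.alphabet else "X"
            bb = b if b in mat.alphabet else "X"
            out[i, j] = int(mat[aa, bb])
    return out


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def scoring_matrix(name: str = "BLOSUM62") -> np.ndarray:
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = _load_matrix(name)
    return _MATRIX_CACHE[name]


_AA_LUT = np.full(256, _AA_INDEX["X"], dtype=np.int16)
for _c, _i in _AA_INDEX.items():
    _AA_LUT[ord(_c)] = _i
    _AA_LUT[ord(_c.lower())] = _i


def encode_protein(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode(), np.uint8)]


@dataclass
class SearchParams:
    """Thresholds and scoring parameters for the translated search."""

    evalue_max: float = 1e-10
    pident_min: float = 25.0
    qcovhsp_min: float = 70.0
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    seed_word_length: int = 4
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    # frames with query_len * frame_len at or below this many DP cells are
    # aligned exhaustively; larger frames go through word seeding
    exhaustive_cell_limit: int = 300_000
    # seeded diagonals whose best ungapped segment scores below this raw
    # score are not extended; must stay well below the minimum raw score a
    # hit can have and still pass the E-value filter (~137 at defaults)
    ungapped_prescreen: int = 60
    band_pad: int = 48

    def __post_init__(self) -> None:
        if not (0 <= self.pident_min <= 100 and 0 <= self.qcovhsp_min <= 100):
            raise ValueError("pident_min and qcovhsp_min must lie in [0, 100]")
        if self.evalue_max <= 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class LocalAlignment:
    """Best-scoring local alignment between two proteins (1-based coords)."""

    score: int
    qstart: int
    qend: int
    sstart: int
    send: int
    identities: int
    aln_length: int


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    genome_id: str
    contig_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    qstart: int
    qend: int
    sstart: int  # 1-based nucleotide coords on the forward strand
    send: int
    raw_score: int
    bitscore: float
    evalue: float
    pident: float
    qcovhsp: float


FRAMES = (1, 2, 3, -1, -2, -3)


# vectorized translation: codon index -> amino-acid byte, built from the
# bacterial/archaeal code (table 11)
def _build_codon_lut() -> np.ndarray:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[11]
    lut = np.zeros(64, dtype=np.uint8)
    bases = "ACGT"
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            for k, c in enumerate(bases):
                codon = a + b + c
                aa = "*" if codon in table.stop_codons else table.forward_table[codon]
                lut[16 * i + 4 * j + k] = ord(aa)
    return lut


_CODON_LUT = _build_codon_lut()
_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i
    _NT_CODE[_b + 32] = _i  # lower case
_NT_COMP = np.array([3, 2, 1, 0, 255], dtype=np.uint8)  # A<->T, C<->G


def _translate_codes(codes: np.ndarray) -> str:
    n = len(codes) // 3 * 3
    if n == 0:
        return ""
    c = codes[:n].reshape(-1, 3)
    valid = (c != 255).all(axis=1)
    idx = (16 * c[:, 0].astype(np.int32) + 4 * c[:, 1] + c[:, 2]) % 64
    aa = _CODON_LUT[idx]
    aa[~valid] = ord("X")
    return aa.tobytes().decode()


def six_frame_translate(contig: str) -> dict[int, str]:
    """Translate a contig in all six frames.

    Frames +1..+3 read the forward strand with offsets 0..2; frames
    -1..-3 read the reverse complement likewise.  Codons containing N (or
    any non-ACGT base) translate to X; stop codons are emitted as '*' and
    retained.
    """
    codes = _NT_CODE[np.frombuffer(contig.encode(), np.uint8)]
    rc = np.minimum(codes[::-1], 4)
    rc = _NT_COMP[rc]
    out: dict[int, str] = {}
    for off in range(3):
        out[off + 1] = _translate_codes(codes[off:])
        out[-(off + 1)] = _translate_codes(rc[off:])
    return out


def evalue(bitscore: float, query_len: int, db_len: int) -> float:
    """Karlin–Altschul expectation E = m*n*2^(-bitscore)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("search-space lengths must be positive")
    return float(query_len) * float(db_len) * math.exp2(-bitscore)


def bitscore(raw_score: float, params: SearchParams) -> float:
    return (params.karlin_lambda * raw_score - math.log(params.karlin_K)) / math.log(2)


# -- exact affine-gap Smith-Waterman --------------------------------------

def _sw_forward(q: np.ndarray, s: np.ndarray, sub: np.ndarray,
                gap_open: int, gap_extend: int):
    """Row-vectorized Gotoh forward pass.

    Returns (H, E, F) score matrices of shape (len(q)+1, len(s)+1).  The
    horizontal state E is computed with a prefix-max scan over donors that
    did not themselves arrive via E (merging consecutive horizontal gaps is
    never worse than reopening, so this is exact).
    """
    nq, ns = len(q), len(s)
    go, ge = gap_open, gap_extend
    S = sub[q][:, s]  # (nq, ns)
    H = np.zeros((nq + 1, ns + 1), dtype=np.int32)
    E = np.empty((nq + 1, ns + 1), dtype=np.int32)
    F = np.empty((nq + 1, ns + 1), dtype=np.int32)
    E[0] = _NEG
    F[0] = _NEG
    E[:, 0] = _NEG
    cols = np.arange(ns + 1, dtype=np.int32)
    gecols = ge * cols
    off_e = go + gecols[1:]
    h0 = np.empty(ns + 1, dtype=np.int32)
    h0[0] = 0
    a = np.empty(ns + 1, dtype=np.int32)
    for i in range(1, nq + 1):
        Hp = H[i - 1]
        Fi = F[i]
        np.maximum(Hp - (go + ge), F[i - 1] - ge, out=Fi)
        np.maximum(Hp[:-1] + S[i - 1], Fi[1:], out=h0[1:])
        np.maximum(h0, 0, out=h0)
        # E[i, j] = max_{k<j} h0[k] - go - (j-k)*ge
        np.add(h0, gecols, out=a)
        np.maximum.accumulate(a, out=a)
        Ei = E[i]
        np.subtract(a[:-1], off_e, out=Ei[1:])
        Hi = H[i]
        np.maximum(h0, Ei, out=Hi)
        Hi[0] = 0
    return H, E, F


def _sw_traceback(q: np.ndarray, s: np.ndarray, H, E, F,
                  gap_open: int, gap_extend: int, sub: np.ndarray) -> LocalAlignment:
    go, ge = gap_open + gap_extend, gap_extend
    end = int(np.argmax(H))
    ncol = H.shape[1]
    i, j = divmod(end, ncol)
    score = int(H[i, j])
    qend, send = i, j
    identities = 0
    aln_length = 0
    v = score
    while v > 0:
        diag = int(H[i - 1, j - 1]) + int(sub[q[i - 1], s[j - 1]]) if i > 0 and j > 0 else _NEG
        if i > 0 and j > 0 and v == diag:
            if q[i - 1] == s[j - 1]:
                identities += 1
            aln_length += 1
            i -= 1
            j -= 1
            v = int(H[i, j])
        elif v == E[i, j]:
            e = int(E[i, j])
            while j > 1 and e == int(E[i, j - 1]) - ge:
                j -= 1
                e += ge
                aln_length += 1
            aln_length += 1
            j -= 1
            v = e + go
        elif v == F[i, j]:
            f = int(F[i, j])
            while i > 1 and f == int(F[i - 1, j]) - ge:
                i -= 1
                f += ge
                aln_length += 1
            aln_length += 1
            i -= 1
            v = f + go
        else:  # v came from the 0 floor
            break
    return LocalAlignment(
        score=score, qstart=i + 1, qend=qend, sstart=j + 1, send=send,
        identities=identities, aln_length=aln_length,
    )


def local_align(query: str, subject: str, params: SearchParams | None = None) -> LocalAlignment | None:
    """Best-scoring affine-gap local alignment, or None if no positive score.

    Exact: the returned score is the Smith–Waterman optimum.  Ties on the
    optimum score resolve to the first maximal cell in row-major order
    (smallest query end, then smallest subject end), with diagonal moves
    preferred during traceback.
    """
    params = params or SearchParams()
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    sub = scoring_matrix(params.substitution_matrix)
    q = encode_protein(query)
    s = encode_protein(subject)
    H, E, F = _sw_forward(q, s, sub, params.gap_open, params.gap_extend)
    if H.max() <= 0:
        return None
    return _sw_traceback(q, s, H, E, F, params.gap_open, params.gap_extend, sub)


# -- word seeding -----------------------------------------------------------

def _word_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer codes over a protein index array; words containing
    ambiguity (X, B, Z) or stops get code -1."""
    n = len(encoded) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    base = np.int64(len(_AA))
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    bad_res = encoded >= _AA_INDEX["B"]  # B, Z, X, *
    for off in range(k):
        codes = codes * base + encoded[off : off + n]
        bad |= bad_res[off : off + n]
    codes[bad] = -1
    return codes


@dataclass
class _QueryIndex:
    names: list[str]
    seqs: list[np.ndarray]
    lengths: np.ndarray
    sorted_codes: np.ndarray  # all query words, sorted
    sorted_query: np.ndarray  # query index per sorted word
    sorted_qpos: np.ndarray   # in-query position per sorted word


def _build_query_index(queries: dict[str, str], k: int) -> _QueryIndex:
    names, seqs, codes_all, qidx_all, qpos_all = [], [], [], [], []
    for qi, (name, seq) in enumerate(queries.items()):
        enc = encode_protein(seq)
        names.append(name)
        seqs.append(enc)
        codes = _word_codes(enc, k)
        keep = codes >= 0
        codes_all.append(codes[keep])
        qpos_all.append(np.nonzero(keep)[0])
        qidx_all.append(np.full(keep.sum(), qi, dtype=np.int64))
    codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
    qidx = np.concatenate(qidx_all) if qidx_all else np.empty(0, np.int64)
    qpos = np.concatenate(qpos_all) if qpos_all else np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")
    return _QueryIndex(
        names=names,
        seqs=seqs,
        lengths=np.array([len(s) for s in seqs], dtype=np.int64),
        sorted_codes=codes[order],
        sorted_query=qidx[order],
        sorted_qpos=qpos[order],
    )


def _seed_matches(frame_enc: np.ndarray, index: _QueryIndex, k: int):
    """All exact word matches between the frame and every query.

    Returns (query_idx, qpos, spos) arrays.
    """
    fcodes = _word_codes(frame_enc, k)
    valid = np.nonzero(fcodes >= 0)[0]
    if valid.size == 0 or index.sorted_codes.size == 0:
        z = np.empty(0, np.int64)
        return z, z, z
    fc = fcodes[valid]
    left = np.searchsorted(index.sorted_codes, fc, side="left")
    right = np.searchsorted(index.sorted_codes, fc, side="right")
    counts = right - left
    hitmask = counts > 0
    if not hitmask.any():
        z = np.empty(0, np.int64)
        return z, z, z
    left, counts, spos = left[hitmask], counts[hitmask], valid[hitmask]
    total = int(counts.sum())
    # expand [left_i, left_i + counts_i) ranges into flat indices
    starts = np.repeat(left, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    flat = starts + within
    return (
        index.sorted_query[flat],
        index.sorted_qpos[flat],
        np.repeat(spos, counts),
    )


def _ungapped_best_batch(qenc: np.ndarray, fenc: np.ndarray, diags: np.ndarray,
                         sub: np.ndarray) -> np.ndarray:
    """Best ungapped segment score for each diagonal d (q[i] vs s[i+d]),
    computed for all diagonals at once (vectorized Kadane)."""
    nq, nf = len(qenc), len(fenc)
    pos = diags[:, None] + np.arange(nq)[None, :]  # (D, nq) subject positions
    valid = (pos >= 0) & (pos < nf)
    strips = sub[qenc[None, :], fenc[np.clip(pos, 0, nf - 1)]].astype(np.int32)
    strips[~valid] = -(10**6)  # segments cannot span off-frame positions
    cs = np.cumsum(strips, axis=1, dtype=np.int64)
    shifted = np.concatenate(
        [np.zeros((len(diags), 1), np.int64), cs[:, :-1]], axis=1
    )
    floor = np.minimum.accumulate(shifted, axis=1)
    return (cs - floor).max(axis=1)


def _candidate_windows(qidx, qpos, spos, index: "_QueryIndex", fenc: np.ndarray,
                       sub: np.ndarray, params: SearchParams):
    """Candidate diagonal bands: seeded diagonals passing the ungapped
    prescreen, grouped per query into bands of nearby diagonals.

    Yields (query_index, diag_min, diag_max) tuples.
    """
    if qidx.size == 0:
        return []
    diag = spos - qpos
    key = qidx * np.int64(2**32) + (diag + np.int64(2**20))
    uniq = np.unique(key)
    uq = (uniq >> 32).astype(np.int64)
    ud = (uniq & (2**32 - 1)).astype(np.int64) - 2**20
    windows = []
    for qi in np.unique(uq):
        ds = ud[uq == qi]
        scores = _ungapped_best_batch(index.seqs[int(qi)], fenc, ds, sub)
        for d in ds[scores >= params.ungapped_prescreen]:
            d = int(d)
            if windows and windows[-1][0] == qi and d - windows[-1][2] <= params.band_pad:
                windows[-1] = (int(qi), windows[-1][1], d)
            else:
                windows.append((int(qi), d, d))
    return windows


# -- genome search ----------------------------------------------------------

def _frame_to_forward_coords(frame: int, aa_start: int, aa_end: int, contig_len: int):
    """Map 1-based aa positions in a translated frame to 1-based forward-
    strand nucleotide coordinates (sstart <= send)."""
    off = abs(frame) - 1
    nt_start = off + 3 * (aa_start - 1) + 1
    nt_end = off + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end
    return contig_len - nt_end + 1, contig_len - nt_start + 1


def search_genome(
    catalog_queries: dict[str, str] | PathwayCatalog,
    genome: GenomeRecord,
    params: SearchParams | None = None,
) -> list[HomologHit]:
    """Search every query against all six frames of every contig.

    Only hits passing all three filters (evalue < evalue_max,
    pident > pident_min, qcovhsp > qcovhsp_min) are returned, and at most
    one hit — the highest bitscore — is retained per query.
    """
    params = params or SearchParams()
    if isinstance(catalog_queries, PathwayCatalog):
        queries = {e.enzyme: e.sequence for e in catalog_queries.enzymes}
        queries.update(catalog_queries.extras)
    else:
        queries = dict(catalog_queries)
    if not queries:
        raise ValueError("query catalog is empty")
    if not genome.contigs:
        return []
    sub = scoring_matrix(params.substitution_matrix)
    k = params.seed_word_length
    index = _build_query_index(queries, k)
    qnames = index.names
    qstrs = list(queries.values())

    # translated search space (total aa over all six frames of all contigs)
    frames_by_contig: dict[str, dict[int, str]] = {
        cid: six_frame_translate(seq) for cid, seq in genome.contigs.items()
    }
    db_len = sum(len(f) for fr in frames_by_contig.values() for f in fr.values())
    if db_len == 0:
        return []

    best: dict[int, tuple] = {}  # query idx -> (raw_score, contig, frame, LocalAlignment)

    def consider(qi: int, contig_id: str, frame: int, aln: LocalAlignment):
        if aln is None or aln.score <= 0:
            return
        key = (-aln.score, contig_id, frame, aln.qstart, aln.sstart)
        cur = best.get(qi)
        if cur is None or key < cur[0]:
            best[qi] = (key, contig_id, frame, aln)

    for contig_id in genome.contigs:
        for frame in FRAMES:
            fstr = frames_by_contig[contig_id][frame]
            if not fstr:
                continue
            fenc = encode_protein(fstr)
            nf = len(fenc)
            # small frames: exhaustive exact alignment for every query
            for qi, qenc in enumerate(index.seqs):
                if len(qenc) * nf <= params.exhaustive_cell_limit:
                    aln = local_align(qstrs[qi], fstr, params)
                    consider(qi, contig_id, frame, aln)
            # large frames: seeded diagonal bands
            big = [qi for qi, qenc in enumerate(index.seqs)
                   if len(qenc) * nf > params.exhaustive_cell_limit]
            if not big:
                continue
            qm, qp, sp = _seed_matches(fenc, index, k)
            bigset = set(big)
            mask = np.isin(qm, np.array(big)) if qm.size else np.zeros(0, bool)
            for qi, dmin, dmax in _candidate_windows(
                qm[mask], qp[mask], sp[mask], index, fenc, sub, params
            ):
                if qi not in bigset:
                    continue
                nq = int(index.lengths[qi])
                s0 = max(0, dmin - params.band_pad)
                s1 = min(nf, dmax + nq + params.band_pad)
                if s1 <= s0:
                    continue
                aln = local_align(qstrs[qi], fstr[s0:s1], params)
                if aln is not None:
                    aln = LocalAlignment(
                        score=aln.score, qstart=aln.qstart, qend=aln.qend,
                        sstart=aln.sstart + s0, send=aln.send + s0,
                        identities=aln.identities, aln_length=aln.aln_length,
                    )
                consider(qi, contig_id, frame, aln)

    hits: list[HomologHit] = []
    for qi in sorted(best):
        _, contig_id, frame, aln = best[qi]
        qlen = int(index.lengths[qi])
        bits = bitscore(aln.score, params)
        ev = evalue(bits, qlen, db_len)
        pident = 100.0 * aln.identities / aln.aln_length
        qcov = 100.0 * (aln.qend - aln.qstart + 1) / qlen
        if not (ev < params.evalue_max and pident > params.pident_min
                and qcov > params.qcovhsp_min):
            continue
        sstart, send = _frame_to_forward_coords(
            frame, aln.sstart, aln.send, len(genome.contigs[contig_id])
        )
        hits.append(HomologHit(
            query_id=qnames[qi], genome_id=genome.genome_id, contig_id=contig_id,
            frame=frame, qstart=aln.qstart, qend=aln.qend,
            sstart=sstart, send=send, raw_score=aln.score,
            bitscore=round(bits, 2), evalue=ev,
            pident=round(pident, 2), qcovhsp=round(qcov, 2),
        ))
    return hits


def hits_to_frame(hits: list[HomologHit]):
    """BLAST outfmt-6-like hit table."""
    import pandas as pd

    cols = ["qseqid", "sseqid", "contig", "pident", "length", "qstart", "qend",
            "sstart", "send", "evalue", "bitscore", "frame", "qcovhsp"]
    rows = [
        [h.query_id, h.genome_id, h.contig_id, h.pident,
         h.qend - h.qstart + 1, h.qstart, h.qend, h.sstart, h.send,
         h.evalue, h.bitscore, h.frame, h.qcovhsp]
        for h in hits
    ]
    return pd.DataFrame(rows, columns=cols)
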
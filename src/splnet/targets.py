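"""Plant-style miRNA target-site prediction by penalty scoring.

The scorer follows the Allen-type convention used by plant target predictors:
each duplex position contributes a penalty (0 for a Watson-Crick pair, 0.5 for
a G:U wobble, 1 for a mismatch, 2 for a gap), penalties are doubled inside the
seed region (miRNA positions 2-13 counted from the 5' end), and a window is
called a site when the minimum total penalty over alignments with at most one
gap falls at or below a cutoff (default 3.0).

Coordinates are 1-based inclusive on the sense strand of the target.  circRNA
back-splice junctions are handled by scanning a junction pseudo-sequence and
mapping hits back to circular coordinates.

Two scoring paths exist on purpose: :func:`duplex_penalty` enumerates the
single-gap alignment structures of one window, while :func:`find_sites` scans
a whole transcript with a vectorised decomposition of the same structure
space; both must (and, in the tests, do) agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .records import TranscriptRecord, normalize_rna, check_nucleotide

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PenaltyScheme:
    """Penalty weights for duplex scoring; all penalties are >= 0."""

    mismatch: float = 1.0
    gu_wobble: float = 0.5
    gap: float = 2.0
    seed_multiplier: float = 2.0
    seed_start: int = 2   # 1-based miRNA position, inclusive
    seed_end: int = 13    # inclusive
    cutoff: float = 3.0
    max_gaps: int = 1

    def __post_init__(self):
        for name in ("mismatch", "gu_wobble", "gap", "seed_multiplier"):
            if getattr(self, name) < 0:
                raise ValidationError(f"penalty {name} must be >= 0")
        if self.seed_start < 1 or self.seed_end < self.seed_start:
            raise ValidationError("invalid seed range")
        if self.max_gaps not in (0, 1):
            raise ValidationError("max_gaps must be 0 or 1")

    def weight(self, mirna_pos: int) -> float:
        """Seed multiplier for a 1-based miRNA position."""
        if self.seed_start <= mirna_pos <= self.seed_end:
            return self.seed_multiplier
        return 1.0


@dataclass
class TargetSite:
    """One predicted miRNA response element (MRE)."""

    mirna_id: str
    target_id: str
    biotype: str
    start: int            # 1-based inclusive, sense strand
    end: int              # may be < start for junction-spanning circRNA sites
    score: float
    duplex: str = ""      # three-line text rendering of the duplex
    spans_junction: bool = False


def _base_penalty(m_base: str, t_base: str, scheme: PenaltyScheme) -> float:
    """Penalty for pairing miRNA base (5'->3') with a target sense base."""
    if t_base == _COMP[m_base]:
        return 0.0
    if (m_base == "G" and t_base == "T") or (m_base == "T" and t_base == "G"):
        return scheme.gu_wobble
    return scheme.mismatch


def _pair_symbol(m_base: str, t_base: str) -> str:
    if t_base == _COMP[m_base]:
        return "|"
    if (m_base == "G" and t_base == "T") or (m_base == "T" and t_base == "G"):
        return "o"
    return " "


def _enumerate_structures(mirna: str, window: str, scheme: PenaltyScheme):
    """Yield (score, columns) for every admissible <=1-gap structure.

    ``window`` is the target subsequence 5'->3'; pairing runs miRNA position j
    against the j-th window base counted from the window's 3' end.  Columns
    are (mirna_char, target_char) with '-' marking gaps, in miRNA 5'->3'
    order.
    """
    L = len(mirna)
    M = len(window)
    rev = window[::-1]  # rev[j-1] = j-th base from the window's 3' end

    def pair_cols(js, ks):
        return [(mirna[j - 1], rev[k - 1]) for j, k in zip(js, ks)]

    if M == L:
        cols = pair_cols(range(1, L + 1), range(1, L + 1))
        score = sum(
            scheme.weight(j) * _base_penalty(m, t, scheme)
            for j, (m, t) in enumerate(cols, start=1)
        )
        yield score, cols
    elif M == L - 1 and scheme.max_gaps >= 1:
        # one miRNA base g left unpaired (gap on the target strand)
        for g in range(1, L + 1):
            cols = []
            score = 0.0
            for j in range(1, L + 1):
                if j == g:
                    cols.append((mirna[j - 1], "-"))
                    score += scheme.weight(j) * scheme.gap
                else:
                    k = j if j < g else j - 1
                    m, t = mirna[j - 1], rev[k - 1]
                    cols.append((m, t))
                    score += scheme.weight(j) * _base_penalty(m, t, scheme)
            yield score, cols
    elif M == L + 1 and scheme.max_gaps >= 1:
        # one target base left unpaired (gap on the miRNA strand), inserted
        # after miRNA position g (g=0: before position 1; g=L: after the end)
        for g in range(0, L + 1):
            cols = []
            score = 0.0
            for j in range(1, g + 1):
                m, t = mirna[j - 1], rev[j - 1]
                cols.append((m, t))
                score += scheme.weight(j) * _base_penalty(m, t, scheme)
            cols.append(("-", rev[g]))
            score += scheme.weight(min(g + 1, L)) * scheme.gap
            for j in range(g + 1, L + 1):
                m, t = mirna[j - 1], rev[j]
                cols.append((m, t))
                score += scheme.weight(j) * _base_penalty(m, t, scheme)
            yield score, cols


def _render_duplex(cols) -> str:
    # display the target 3'->5' so paired columns line up with miRNA 5'->3'
    m_line = "".join(m for m, _ in cols)
    t_line = "".join(t for _, t in cols)
    sym = "".join(
        _pair_symbol(m, t) if "-" not in (m, t) else " " for m, t in cols
    )
    return (f"miRNA  5' {m_line} 3'\n"
            f"          {sym}\n"
            f"target 3' {t_line} 5'")


def duplex_penalty(
    mirna: str, window: str, scheme: PenaltyScheme = PenaltyScheme()
) -> Tuple[float, str]:
    """Minimum penalty of aligning a miRNA against one target window.

    Parameters
    ----------
    mirna : str
        Mature miRNA, 5'->3'.  T and U are equivalent.
    window : str
        Target subsequence (sense strand, 5'->3') whose length must lie in
        ``[len(mirna) - max_gaps, len(mirna) + max_gaps]``.

    Returns
    -------
    (score, duplex) : the minimum total penalty and a text rendering of the
    optimal duplex (ties broken toward the 5'-most gap placement).
    """
    mirna = check_nucleotide(mirna)
    window = check_nucleotide(window)
    L, M = len(mirna), len(window)
    if not (L - scheme.max_gaps <= M <= L + scheme.max_gaps):
        raise ValidationError(
            f"window length {M} outside [{L - scheme.max_gaps}, "
            f"{L + scheme.max_gaps}] for a {L} nt miRNA"
        )
    if L > M and scheme.max_gaps == 0:
        raise ValidationError("window shorter than miRNA with max_gaps=0")
    best = None
    for score, cols in _enumerate_structures(mirna, window, scheme):
        if best is None or score < best[0]:
            best = (score, cols)
    if best is None:
        raise ValidationError("no admissible alignment for window length")
    return best[0], _render_duplex(best[1])


def _penalty_table(mirna: str, scheme: PenaltyScheme) -> np.ndarray:
    """(L, 4) matrix: seed-weighted penalty of pairing m[j] with each base."""
    L = len(mirna)
    table = np.empty((L, 4))
    for j in range(L):
        w = scheme.weight(j + 1)
        for base, code in _CODE.items():
            table[j, code] = w * _base_penalty(mirna[j], base, scheme)
    return table


_BIG = 1e9  # finite sentinel: keeps cumulative sums well-defined


def _scan_scores(mirna: str, target: str, scheme: PenaltyScheme):
    """Vectorised minimum penalty per (end position, window length).

    Returns a dict mapping window length (L-1, L, L+1) to an array indexed by
    0-based end position ``e`` on the target, holding the minimum penalty over
    all admissible structures of that length ending at ``e`` (``_BIG`` where
    no window fits).
    """
    L = len(mirna)
    T = len(target)
    tc = np.fromiter((_CODE[c] for c in target), dtype=np.int64, count=T)
    pen = _penalty_table(mirna, scheme)

    # C[j, x] = penalty of pairing miRNA position j+1 with target base
    # tc[x - j]; column index x equals the 0-based end position for the
    # ungapped register.
    width = T + L + 2
    C = np.full((L, width), _BIG)
    for j in range(L):
        C[j, j:j + T] = pen[j, tc]
    # pre[g, x] = sum of C[0:g, x]; suf[g, x] = sum of C[g:L, x]
    pre = np.zeros((L + 1, width))
    pre[1:] = np.cumsum(C, axis=0)
    suf = np.zeros((L + 2, width))
    suf[:L] = np.cumsum(C[::-1], axis=0)[::-1]

    out = {}
    e = np.arange(T)  # candidate 0-based end positions
    s0 = pre[L, :T]
    s0 = np.where(e >= L - 1, s0, _BIG)
    out[L] = np.minimum(s0, _BIG)

    if scheme.max_gaps >= 1:
        # window length L-1: miRNA base g unpaired (target-strand gap)
        w = np.array([scheme.weight(j) for j in range(1, L + 1)])
        tg = np.full(T, _BIG)
        sufp = np.full((L + 2, width), _BIG)
        sufp[:, :-1] = suf[:, 1:]
        for g in range(1, L + 1):
            cand = pre[g - 1, :T] + w[g - 1] * scheme.gap + sufp[g, :T]
            tg = np.minimum(tg, cand)
        tg = np.where(e >= L - 2, tg, _BIG)
        out[L - 1] = np.minimum(tg, _BIG)

        # window length L+1: one target base unpaired (miRNA-strand gap)
        mg = np.full(T, _BIG)
        sufm = np.full((L + 2, width), _BIG)
        sufm[:, 1:] = suf[:, :-1]
        for g in range(0, L + 1):
            wg = scheme.weight(min(g + 1, L))
            cand = pre[g, :T] + wg * scheme.gap + sufm[g, :T]
            mg = np.minimum(mg, cand)
        mg = np.where(e >= L, mg, _BIG)
        out[L + 1] = np.minimum(mg, _BIG)
    return out


def find_sites(
    mirna_id: str,
    mirna: str,
    transcript: TranscriptRecord,
    scheme: PenaltyScheme = PenaltyScheme(),
    *,
    sequence: Optional[str] = None,
) -> List[TargetSite]:
    """All windows of a transcript scoring at or below the cutoff.

    Overlapping calls are resolved to the lowest-scoring site (ties to the
    leftmost); the result is sorted by start coordinate.  ``sequence``
    overrides the scanned sequence (used for junction pseudo-sequences).
    """
    mirna = check_nucleotide(mirna)
    seq = normalize_rna(sequence if sequence is not None else transcript.seq)
    L = len(mirna)
    if len(seq) < L - scheme.max_gaps:
        raise ValidationError(
            f"transcript {transcript.id} shorter than miRNA - max_gaps"
        )
    per_length = _scan_scores(mirna, seq, scheme)
    candidates = []
    for wlen, scores in per_length.items():
        hits = np.nonzero(scores <= scheme.cutoff)[0]
        for e in hits:
            start = int(e) - wlen + 2  # 1-based
            if start < 1:
                continue
            window = seq[start - 1:int(e) + 1]
            score, duplex = duplex_penalty(mirna, window, scheme)
            candidates.append(TargetSite(
                mirna_id=mirna_id, target_id=transcript.id,
                biotype=transcript.biotype, start=start, end=int(e) + 1,
                score=score, duplex=duplex,
            ))
    # overlap resolution: accept best-scoring first, leftmost on ties
    candidates.sort(key=lambda s: (s.score, s.start, s.end))
    accepted: List[TargetSite] = []
    for site in candidates:
        if all(site.end < a.start or site.start > a.end for a in accepted):
            accepted.append(site)
    accepted.sort(key=lambda s: s.start)
    return accepted


def circ_junction_sequence(
    circ: TranscriptRecord, flank: int
) -> Tuple[str, Dict[int, int]]:
    """Back-splice junction context of a circRNA.

    Returns the pseudo-sequence made of the ``flank`` bases upstream of the
    junction followed by the ``flank`` bases downstream of it (walking the
    circle), plus a map from 1-based pseudo-positions to 1-based circular
    positions.
    """
    if circ.biotype != "circrna" or circ.junction is None:
        raise ValidationError(f"{circ.id} is not a circRNA with a junction")
    n = len(circ.seq)
    if flank >= n:
        raise ValidationError(
            f"flank {flank} must be smaller than the circle length {n}"
        )
    j = circ.junction
    positions: List[int] = []
    for k in range(flank, 0, -1):          # j-k+1 .. j  (upstream side)
        positions.append(((j - k) % n) + 1)
    for k in range(1, flank + 1):          # j+1 .. j+flank (downstream side)
        positions.append(((j + k - 1) % n) + 1)
    pseudo = "".join(circ.seq[p - 1] for p in positions)
    coord_map = {i + 1: p for i, p in enumerate(positions)}
    return pseudo, coord_map


def find_circ_sites(
    mirna_id: str,
    mirna: str,
    circ: TranscriptRecord,
    scheme: PenaltyScheme = PenaltyScheme(),
) -> List[TargetSite]:
    """Linear plus junction-spanning sites of a circRNA, deduplicated.

    Sites are reported in circular coordinates; a site whose pseudo-sequence
    span crosses the back-splice join carries ``spans_junction=True`` (its
    circular end coordinate then wraps below its start).
    """
    mirna = check_nucleotide(mirna)
    L = len(mirna)
    sites = {
        (s.start): s
        for s in find_sites(mirna_id, mirna, circ, scheme)
    }
    flank = L + scheme.max_gaps - 1
    if flank < len(circ.seq):
        pseudo, coord_map = circ_junction_sequence(circ, flank)
        boundary = flank  # join sits between pseudo positions flank, flank+1
        for s in find_sites(mirna_id, mirna, circ, scheme, sequence=pseudo):
            spans = s.start <= boundary < s.end
            mapped = replace(
                s,
                start=coord_map[s.start],
                end=coord_map[s.end],
                spans_junction=spans,
            )
            prev = sites.get(mapped.start)
            if prev is None or mapped.score < prev.score:
                sites[mapped.start] = mapped
    out = list(sites.values())
    out.sort(key=lambda s: s.start)
    return out


def predict_targetome(
    mirnas: Sequence[TranscriptRecord],
    transcripts: Sequence[TranscriptRecord],
    scheme: PenaltyScheme = PenaltyScheme(),
):
    """MRE table over all (miRNA, transcript) pairs as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for mi in mirnas:
        for tr in transcripts:
            if tr.biotype == "mirna":
                continue
            if len(tr.seq) < len(mi.seq) - scheme.max_gaps:
                continue
            if tr.biotype == "circrna":
                sites = find_circ_sites(mi.id, mi.seq, tr, scheme)
            else:
                sites = find_sites(mi.id, mi.seq, tr, scheme)
            for s in sites:
                rows.append({
                    "mirna_id": s.mirna_id, "target_id": s.target_id,
                    "biotype": s.biotype, "start": s.start, "end": s.end,
                    "score": s.score, "spans_junction": s.spans_junction,
                })
    columns = ["mirna_id", "target_id", "biotype", "start", "end", "score",
               "spans_junction"]
    table = pd.DataFrame(rows, columns=columns)
    table = table.drop_duplicates(subset=["mirna_id", "target_id", "start"])
    return table.sort_values(
        ["mirna_id", "target_id", "start"]
    ).reset_index(drop=True)
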
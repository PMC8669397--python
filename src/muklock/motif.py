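"""matS-site discovery: approximate motif scanning, GC skew, family ranking.

The discovery procedure mirrors how signature sites of the replication
terminus macrodomain are found on an unannotated chromosome: scan for all
loci within a small edit distance of a palindromic query (or all exact
matches of a degenerate pattern with N wildcards), predict the replication
terminus from the cumulative GC skew curve, and rank candidate site
families by their median circular distance to the terminus. Families
clustering at the terminus are matS candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from muklock.errors import DataError
from muklock.genome import CircularGenome, reverse_complement

_DNA = set("ACGT")
_IUPAC_N = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ScanParameters:
    """Parameters of a motif scan.

    ``pattern`` may contain N wildcards only in degenerate mode
    (``max_edit == 0``); in edit mode the query must be concrete because
    Levenshtein distance to a wildcard is undefined here.
    """

    pattern: str
    max_edit: int = 0
    both_strands: bool = True
    collapse_overlaps: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise DataError("pattern must be non-empty")
        bad = set(self.pattern) - _IUPAC_N
        if bad:
            raise DataError(f"pattern contains invalid characters: {sorted(bad)}")
        if self.max_edit < 0:
            raise DataError("max_edit must be >= 0")
        if self.max_edit > 0 and "N" in self.pattern:
            raise DataError("N wildcards are only allowed with max_edit=0")


@dataclass(frozen=True)
class MotifHit:
    """A located motif match on the forward-strand coordinate system."""

    start: int
    length: int
    strand: str
    edit_distance: int
    matched_seq: str


@dataclass(frozen=True)
class SkewProfile:
    """Cumulative GC skew with called replication origin and terminus.

    ``cumulative[i]`` is the running sum of per-window skews
    ``(nG - nC) / (nG + nC)`` over the first ``i + 1`` windows. The
    terminus is called at the global maximum of the cumulative curve, the
    origin at the global minimum (leading-strand G-bias convention).
    ``ori_pos``/``ter_pos`` are ``None`` when the curve is flat.
    """

    window: int
    step: int
    cumulative: np.ndarray
    window_positions: np.ndarray
    ori_pos: int | None
    ter_pos: int | None


@dataclass(frozen=True)
class SiteFamilyRanking:
    """Families sorted by median circular distance to the terminus."""

    entries: tuple  # of (family_pattern, n_hits, median_ter_distance, rank)


# ---------------------------------------------------------------------------
# edit distance and identity


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two DNA strings (unit-cost edits)."""
    for s in (a, b):
        bad = set(s) - _DNA
        if bad:
            raise DataError(f"edit_distance: invalid characters {sorted(bad)}")
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def global_identity(a: str, b: str, alphabet: str = "auto") -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    Scoring is match +1, mismatch 0, linear gap -1. The identity is
    100 x matches / alignment columns, counting gap columns in the
    denominator, so the result is in [0, 100].
    """
    if not a or not b:
        raise DataError("global_identity: sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


# ---------------------------------------------------------------------------
# motif scanning


def _wildcard_hits(text: str, pattern: str, n_report: int) -> list[int]:
    """Start positions (< n_report) where pattern matches with N wildcards."""
    m = len(pattern)
    if len(text) < m:
        return []
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    ok = np.ones(windows.shape[0], dtype=bool)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    for j in range(m):
        if pattern[j] != "N":
            ok &= windows[:, j] == p[j]
    starts = np.flatnonzero(ok)
    return [int(s) for s in starts if s < n_report]


def _edit_hits(text: str, pattern: str, k: int, n_report: int) -> list[tuple[int, int, int]]:
    """Approximate occurrences of ``pattern`` in ``text``.

    Returns (start, best_distance, best_window_length) for every start
    position < ``n_report`` whose window of some length in
    [len(pattern)-k, len(pattern)+k] is within edit distance k.

    Pigeonhole seed-and-verify: a match with <= k errors must contain one
    of k+1 contiguous pattern pieces exactly; exact piece hits nominate
    candidate starts which are verified with full Levenshtein alignments.
    """
    m = len(pattern)
    n = len(text)
    if n < max(1, m - k):
        return []
    if k == 0:
        return [(s, 0, m) for s in _wildcard_hits(text, pattern, n_report)]

    # split the pattern into k+1 near-equal pieces
    bounds = np.linspace(0, m, k + 2).astype(int)
    candidates: set[int] = set()
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    for lo, hi in zip(bounds[:-1].tolist(), bounds[1:].tolist()):
        piece = pattern[lo:hi]
        lp = len(piece)
        if lp == 0 or n < lp:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, lp)
        p = np.frombuffer(piece.encode(), dtype=np.uint8)
        occ = np.flatnonzero((windows == p).all(axis=1))
        # a piece at pattern offset lo may be displaced by up to k edits
        for o in occ:
            base = int(o) - lo
            for d in range(-k, k + 1):
                s = base + d
                if 0 <= s < n_report:
                    candidates.add(s)

    out = []
    for s in sorted(candidates):
        best = None
        for length in range(max(0, m - k), m + k + 1):
            if s + length > n:
                break
            w = text[s:s + length]
            d = m if not w else edlib.align(pattern, w, task="distance")["editDistance"]
            if best is None or d < best[0]:
                best = (d, length)
        if best is not None and best[0] <= k:
            out.append((s, best[0], best[1]))
    return out


def _collapse(hits: list[MotifHit], pattern_len: int) -> list[MotifHit]:
    """Merge overlapping hits (starts closer than the pattern length).

    Within each cluster keep the minimum edit distance, then the smallest
    start.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, h.edit_distance))
    clusters: list[list[MotifHit]] = [[hits[0]]]
    for h in hits[1:]:
        if h.start - clusters[-1][-1].start < pattern_len:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    out = []
    for cl in clusters:
        out.append(min(cl, key=lambda h: (h.edit_distance, h.start)))
    return out


def scan_motifs(genome: CircularGenome, params: ScanParameters) -> list[MotifHit]:
    """Scan a genome for approximate or degenerate occurrences of a pattern.

    Degenerate mode (``max_edit == 0``): every locus where the window
    matches the pattern with N as wildcard. Edit mode: every locus whose
    window (of length |pattern| +- max_edit) is within ``max_edit``
    Levenshtein distance, reporting the minimum distance per locus.
    Circular genomes are scanned across the origin. Palindromic patterns
    are reported once per forward-strand locus.
    """
    pattern = params.pattern.upper()
    m = len(pattern)
    n = len(genome)
    k = params.max_edit
    if m > n:
        raise DataError("pattern longer than genome")

    # extension so windows crossing the origin are seen exactly once
    if genome.circular:
        ext = min(n - 1, m + k - 1)
        text = genome.seq + genome.seq[:ext]
    else:
        text = genome.seq

    palindromic = "N" not in pattern and reverse_complement(pattern) == pattern
    if "N" in pattern:
        rc = reverse_complement(pattern)
        palindromic = rc == pattern  # N maps to N under complement

    queries = [(pattern, "+")]
    if params.both_strands and not palindromic:
        rc = reverse_complement(pattern)
        if rc != pattern:
            queries.append((rc, "-"))

    all_hits: list[MotifHit] = []
    for query, strand in queries:
        for s, d, length in _edit_hits(text, query, k, n):
            all_hits.append(
                MotifHit(start=s, length=length, strand=strand,
                         edit_distance=d, matched_seq=text[s:s + length])
            )

    if params.collapse_overlaps:
        all_hits = _collapse(all_hits, m)
    else:
        all_hits = sorted(all_hits, key=lambda h: (h.start, h.strand))
    return all_hits


# ---------------------------------------------------------------------------
# GC skew


def cumulative_gc_skew(genome: CircularGenome, window: int = 1000,
                       step: int | None = None) -> SkewProfile:
    """Cumulative GC skew profile with ori/ter calls.

    Per-window skew is ``(nG - nC) / (nG + nC)`` (0 for GC-free windows);
    the cumulative curve is its running sum. For the conventional
    leading-strand G bias, the curve attains its global maximum at the
    replication terminus and its global minimum at the origin. Window
    positions are the (rounded-up) genomic midpoints of each window; ties
    between equal extrema are broken toward the smallest coordinate.
    """
    n = len(genome)
    if step is None:
        step = window
    if not (1 <= window <= n):
        raise DataError("window must satisfy 1 <= window <= genome length")
    if not (1 <= step <= window):
        raise DataError("step must satisfy 1 <= step <= window")

    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])

    if genome.circular:
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
    if starts.size == 0:
        raise DataError("no complete windows fit in the genome")

    def counts(cum: np.ndarray, s: np.ndarray) -> np.ndarray:
        e = s + window
        inside = np.minimum(e, n)
        c = cum[inside] - cum[s]
        wrap = np.maximum(e - n, 0)
        return c + cum[wrap]

    ng = counts(cg, starts)
    nc = counts(cc, starts)
    tot = ng + nc
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(tot > 0, (ng - nc) / np.maximum(tot, 1), 0.0)
    cumulative = np.cumsum(skew)
    positions = (starts + (window + 1) // 2) % n

    if np.allclose(skew, 0.0):
        ori = ter = None
    else:
        ter = int(positions[int(np.argmax(cumulative))])
        ori = int(positions[int(np.argmin(cumulative))])
    return SkewProfile(window=window, step=step, cumulative=cumulative,
                       window_positions=positions, ori_pos=ori, ter_pos=ter)


def circular_distance(i: int, j: int, length: int) -> int:
    """Shortest distance between two coordinates on a circle of given length."""
    if length <= 0:
        raise DataError("length must be positive")
    if not (0 <= i < length and 0 <= j < length):
        raise DataError("coordinates must lie in [0, length)")
    d = abs(i - j)
    return min(d, length - d)


def rank_site_families(
    families: Mapping[str, Sequence[MotifHit]],
    ter_pos: int,
    genome_length: int,
) -> SiteFamilyRanking:
    """Rank motif families by median circular distance of hits to the terminus.

    Hit midpoints (``start + length // 2``) are used as site coordinates.
    Rank 1 is the family closest to the terminus; ties are broken
    lexicographically by pattern.
    """
    if not families:
        raise DataError("no families to rank")
    rows = []
    for pattern, hits in families.items():
        if len(hits) == 0:
            raise DataError(f"family {pattern} has no hits")
        dists = [
            circular_distance((h.start + h.length // 2) % genome_length,
                              ter_pos, genome_length)
            for h in hits
        ]
        rows.append((pattern, len(hits), float(np.median(dists))))
    rows.sort(key=lambda r: (r[2], r[0]))
    entries = tuple(
        (pattern, n_hits, med, rank + 1)
        for rank, (pattern, n_hits, med) in enumerate(rows)
    )
    return SiteFamilyRanking(entries=entries)
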
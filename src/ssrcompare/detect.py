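"""Detection of perfect and imperfect microsatellite tracts.

A reported tract must span at least ``min_tract_length`` nucleotides
(default 20) with a repeat unit of 1-6 nt.  Imperfection is modelled as
substitution noise: for a candidate tract and period ``p`` the positions are
grouped into ``p`` phase classes, the consensus unit takes the majority base
of each class (ties resolved alphabetically), and every position disagreeing
with the periodic extrapolation of that consensus counts as one mismatch.
A tract qualifies when ``mismatches <= tolerance * length`` and is reported
only if *maximal* -- extending it one nucleotide left or right would break
the tolerance bound or run off the sequence.  ``N`` bases never match
anything and consume tolerance budget.  Insertions/deletions inside tracts
are not modelled.

Overlapping explanations of the same locus (e.g. a poly-A run seen at
periods 1, 2 and 3) are reduced to a single hit by
:func:`resolve_overlaps`.  :func:`oracle_find_ssrs` is a brute-force
re-implementation over all substrings, kept for cross-validation on short
sequences.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .motifs import MotifClass, canonicalize, primitive_root

_ORACLE_MAX_LENGTH = 500
_TOL_EPS = 1e-9

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_N_CODE = 4


class InvalidSequenceError(ValueError):
    """Sequence contained characters outside {A, C, G, T, N}."""


def _encode(seq: str) -> np.ndarray:
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise InvalidSequenceError(f"non-ASCII character in sequence: {exc}") from None
    enc = _ENCODE[raw]
    bad = np.flatnonzero(enc == 255)
    if bad.size:
        raise InvalidSequenceError(
            f"illegal character {seq[bad[0]]!r} at position {int(bad[0])} "
            "(expected A/C/G/T/N)"
        )
    return enc


@dataclass(frozen=True)
class DetectorConfig:
    """Detection parameters.

    min_tract_length: minimum reported tract span in nucleotides.
    min_unit / max_unit: repeat-unit period range (1-6 nt).
    tolerance: admissible per-tract mismatch fraction in [0, 0.5).
    min_seed_run: internal seeding parameter -- minimum run of matching
        lag positions used to nucleate perfect-tract search.  Purely an
        implementation detail; it never changes the reported hit set.
    """

    min_tract_length: int = 20
    min_unit: int = 1
    max_unit: int = 6
    tolerance: float = 0.0
    min_seed_run: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.min_unit <= self.max_unit <= 6:
            raise ValueError("require 1 <= min_unit <= max_unit <= 6")
        if not 0.0 <= self.tolerance < 0.5:
            raise ValueError("tolerance must lie in [0, 0.5)")
        if self.min_tract_length < self.max_unit:
            raise ValueError("min_tract_length must be >= max_unit")
        if self.min_seed_run < 1:
            raise ValueError("min_seed_run must be >= 1")


@dataclass(frozen=True)
class SsrHit:
    """A maximal microsatellite tract.

    Coordinates are 0-based half-open on the input sequence; ``found_unit``
    is the consensus unit phased at the tract start (the rotation a reader
    sees at ``start``), and the canonical class is available via ``motif``.
    """

    sequence_id: str
    start: int
    end: int
    found_unit: str
    mismatch_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def period(self) -> int:
        return len(self.found_unit)

    @property
    def copy_number(self) -> float:
        return self.length / self.period

    @property
    def purity(self) -> float:
        return 1.0 - self.mismatch_count / self.length

    @cached_property
    def motif(self) -> MotifClass:
        return canonicalize(self.found_unit, reduce=True)

    def sort_key(self) -> tuple:
        return (self.sequence_id, self.start, self.end, self.period)


def _within_tolerance(mismatches: float, length: float, tolerance: float) -> bool:
    return mismatches <= tolerance * length + _TOL_EPS


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open intervals."""
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _lag_matches(enc: np.ndarray, period: int) -> np.ndarray:
    """Boolean lag profile: position ``i`` matches position ``i + period``."""
    if period >= len(enc):
        return np.zeros(0, dtype=bool)
    return (enc[:-period] == enc[period:]) & (enc[:-period] != _N_CODE)


def autocorrelation_seed(
    seq: "str | np.ndarray", period: int, config: DetectorConfig
) -> list[tuple[int, int]]:
    """Maximal runs of lag-``period`` self-matches, at least ``min_seed_run`` long.

    Runs are reported as half-open intervals over the lag profile
    (position ``i`` covers the comparison of ``seq[i]`` with
    ``seq[i + period]``).
    """
    enc = _encode(seq) if isinstance(seq, str) else seq
    matches = _lag_matches(enc, period)
    return [r for r in _bool_runs(matches) if r[1] - r[0] >= config.min_seed_run]


def _phase_prefix_counts(enc: np.ndarray, period: int) -> np.ndarray:
    """``P[b, q, i]`` = count of base ``b`` among positions ``< i`` in phase class ``q``.

    Phase classes are defined globally as ``position mod period`` so that
    windows sharing a boundary use consistent bookkeeping.
    """
    n = len(enc)
    P = np.zeros((4, period, n + 1), dtype=np.int32)
    phases = np.arange(n) % period
    for b in range(4):
        is_b = enc == b
        for q in range(period):
            P[b, q, 1:] = np.cumsum(is_b & (phases == q))
    return P


def _consensus_unit(P: np.ndarray, period: int, start: int, end: int) -> str:
    """Majority base per phase class over ``[start, end)``, phased at ``start``."""
    bases = []
    for j in range(period):
        q = (start + j) % period
        counts = P[:, q, end] - P[:, q, start]
        bases.append("ACGT"[int(np.argmax(counts))])  # argmax ties -> alphabetical
    return "".join(bases)


def _perfect_tracts(
    enc: np.ndarray, period: int, config: DetectorConfig
) -> list[tuple[int, int, int]]:
    """Maximal zero-mismatch tracts of the given period, as (start, end, 0)."""
    min_run = config.min_tract_length - period
    seed_cfg = dataclasses.replace(
        config, min_seed_run=min(config.min_seed_run, max(min_run, 1))
    )
    out = []
    for a, b in autocorrelation_seed(enc, period, seed_cfg):
        if b - a >= min_run:
            out.append((a, b + period, 0))
    return out


def _tolerant_tracts(
    enc: np.ndarray, period: int, config: DetectorConfig, P: np.ndarray
) -> list[tuple[int, int, int]]:
    """All maximal tracts at period ``p`` under a positive tolerance.

    Exact row scan: for each candidate start ``s`` the mismatch count
    ``mm(s, e)`` is evaluated for every end in one vectorized pass, and a
    tract is kept when it qualifies but neither single-nucleotide extension
    does.  Rows are pruned with a necessary condition on the lag-mismatch
    density: each consensus mismatch can break at most two lag comparisons,
    so a qualifying tract ``(s, e)`` needs
    ``zeros(s, e - p) <= 2 * tolerance * (e - s)``; a suffix minimum of the
    rearranged inequality rules out most starts in O(1).
    """
    n = len(enc)
    min_len = config.min_tract_length
    tol = config.tolerance
    if n < min_len or period >= n:
        return []

    matches = _lag_matches(enc, period)
    zeros_prefix = np.concatenate(([0], np.cumsum(~matches)))  # len n - p + 1
    # g[e] = zeros_prefix[e - p] - 2 * tol * e for feasible tract ends e
    ends = np.arange(min_len, n + 1)
    g = zeros_prefix[ends - period] - 2.0 * tol * ends
    # suffix_min_g[s] = min over e >= max(s + min_len, min_len) of g[e]
    suffix_min = np.minimum.accumulate(g[::-1])[::-1]

    hits: list[tuple[int, int, int]] = []
    e_axis = np.arange(n + 1)
    prev_qual: np.ndarray | None = None
    for s in range(0, n - min_len + 1):
        bound = zeros_prefix[s] - 2.0 * tol * s + _TOL_EPS
        idx = max(s + min_len, min_len) - min_len
        if suffix_min[idx] > bound:
            prev_qual = None  # row has no qualifying window; neither can s-1 end here
            continue
        window_counts = P[:, :, s:] - P[:, :, s][:, :, None]  # (4, p, n + 1 - s)
        mm_row = np.empty(n + 1, dtype=np.int64)
        mm_row[:s] = np.iinfo(np.int64).max
        mm_row[s:] = (e_axis[s:] - s) - window_counts.max(axis=0).sum(axis=0)
        lengths = e_axis - s
        qual = (lengths >= min_len) & (mm_row <= tol * lengths + _TOL_EPS)
        if qual.any():
            right_max = qual.copy()
            right_max[:-1] &= ~qual[1:]
            if prev_qual is not None:
                right_max &= ~prev_qual
            for e in np.flatnonzero(right_max):
                hits.append((s, int(e), int(mm_row[e])))
        prev_qual = qual if qual.any() else None
    return hits


def _build_hits(
    enc: np.ndarray,
    period: int,
    raw: list[tuple[int, int, int]],
    P: np.ndarray | None,
    sequence_id: str,
) -> list[SsrHit]:
    hits = []
    for s, e, mm in raw:
        if P is not None:
            unit = _consensus_unit(P, period, s, e)
        else:  # perfect tract: the observed unit is the consensus
            unit = "".join("ACGTN"[c] for c in enc[s : s + period])
        if len(primitive_root(unit)) < period:
            continue  # same tract is represented at its primitive period
        hits.append(SsrHit(sequence_id, s, e, unit, mm))
    return hits


def find_ssrs(
    seq: str,
    config: DetectorConfig | None = None,
    sequence_id: str = "seq",
    resolve: bool = True,
) -> list[SsrHit]:
    """Find all maximal perfect/imperfect microsatellite tracts in ``seq``.

    Returns hits sorted by (start, end, period) after overlap resolution;
    ``resolve=False`` keeps every per-period maximal tract (for which
    containment is monotone in tolerance).
    """
    cfg = config or DetectorConfig()
    enc = _encode(seq)
    if len(enc) < cfg.min_tract_length:
        return []
    all_hits: list[SsrHit] = []
    for p in range(cfg.min_unit, cfg.max_unit + 1):
        if cfg.tolerance <= 0.0:
            raw = _perfect_tracts(enc, p, cfg)
            all_hits.extend(_build_hits(enc, p, raw, None, sequence_id))
        else:
            P = _phase_prefix_counts(enc, p)
            raw = _tolerant_tracts(enc, p, cfg, P)
            all_hits.extend(_build_hits(enc, p, raw, P, sequence_id))
    if resolve:
        all_hits = resolve_overlaps(all_hits)
    return sorted(all_hits, key=SsrHit.sort_key)


def resolve_overlaps(hits: list[SsrHit]) -> list[SsrHit]:
    """Keep one explanation per locus.

    Two hits conflict when their intervals overlap by more than half of the
    shorter hit.  Conflicts are resolved greedily in priority order: fewer
    mismatches per base, then longer tract, then smaller period, then
    smaller start coordinate.
    """

    def priority(h: SsrHit) -> tuple:
        return (h.mismatch_count / h.length, -h.length, h.period, h.start, h.end)

    kept: list[SsrHit] = []
    for hit in sorted(hits, key=priority):
        conflict = False
        for other in kept:
            if other.sequence_id != hit.sequence_id:
                continue
            overlap = min(hit.end, other.end) - max(hit.start, other.start)
            if overlap > 0 and 2 * overlap > min(hit.length, other.length):
                conflict = True
                break
        if not conflict:
            kept.append(hit)
    return sorted(kept, key=SsrHit.sort_key)


def oracle_find_ssrs(
    seq: str, config: DetectorConfig | None = None, sequence_id: str = "seq"
) -> list[SsrHit]:
    """Brute-force reference detector for cross-validation (test use).

    Enumerates *every* substring at every period, checks the mismatch bound
    directly on the full (start, end) matrix, keeps maximal qualifying
    tracts and applies the same overlap resolution.  Quadratic in sequence
    length; refuses inputs longer than 500 nt.
    """
    cfg = config or DetectorConfig()
    n = len(seq)
    if n > _ORACLE_MAX_LENGTH:
        raise ValueError(f"oracle is quadratic; sequence of {n} nt exceeds {_ORACLE_MAX_LENGTH}")
    enc = _encode(seq)
    if n < cfg.min_tract_length:
        return []
    all_hits: list[SsrHit] = []
    coords = np.arange(n + 1)
    lengths = coords[None, :] - coords[:, None]  # L[s, e] = e - s
    for p in range(cfg.min_unit, cfg.max_unit + 1):
        if p >= n:
            continue
        P = _phase_prefix_counts(enc, p)
        counts = P[:, :, None, :] - P[:, :, :, None]  # (4, p, s, e)
        mm = lengths - counts.max(axis=0).sum(axis=0)
        qual = (lengths >= cfg.min_tract_length) & (
            mm <= cfg.tolerance * lengths + _TOL_EPS
        )
        ext_left = np.zeros_like(qual)
        ext_left[1:, :] = qual[:-1, :]
        ext_right = np.zeros_like(qual)
        ext_right[:, :-1] = qual[:, 1:]
        maximal = qual & ~ext_left & ~ext_right
        raw = [(int(s), int(e), int(mm[s, e])) for s, e in zip(*np.nonzero(maximal))]
        all_hits.extend(_build_hits(enc, p, raw, P, sequence_id))
    return sorted(resolve_overlaps(all_hits), key=SsrHit.sort_key)


def check_hit(seq: str, hit: SsrHit, config: DetectorConfig) -> list[str]:
    """Re-verify every invariant of an emitted hit; returns violations (test aid)."""
    enc = _encode(seq)
    problems = []
    if hit.length < config.min_tract_length:
        problems.append(f"tract shorter than {config.min_tract_length}")
    p = hit.period
    P = _phase_prefix_counts(enc, p)

    def mismatches(s: int, e: int) -> int:
        counts = P[:, :, e] - P[:, :, s]
        return (e - s) - int(counts.max(axis=0).sum())

    mm = mismatches(hit.start, hit.end)
    if mm != hit.mismatch_count:
        problems.append(f"recorded {hit.mismatch_count} mismatches, recomputed {mm}")
    if not _within_tolerance(mm, hit.length, config.tolerance):
        problems.append("tract violates the tolerance bound")
    if hit.start > 0 and _within_tolerance(
        mismatches(hit.start - 1, hit.end), hit.length + 1, config.tolerance
    ):
        problems.append("tract extensible to the left")
    if hit.end < len(enc) and _within_tolerance(
        mismatches(hit.start, hit.end + 1), hit.length + 1, config.tolerance
    ):
        problems.append("tract extensible to the right")
    if _consensus_unit(P, p, hit.start, hit.end) != hit.found_unit:
        problems.append("found_unit is not the phased consensus")
    if len(primitive_root(hit.found_unit)) != p:
        problems.append("found_unit is not primitive")
    return problems
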
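"""The five evidence scorers for E3-substrate interaction prediction.

* ortholog transfer of known interactions from a second species
* enrichment of (E3-side label, substrate-side label) annotation pairs
  among known interactions -- one formula serving both the protein-domain
  and the GO-term namespaces
* triangle (N3) and quadrilateral (N4) counts through the query edge in
  the PPI network augmented with that edge
* greedy discovery of ungapped linear recognition motifs per E3, scored by
  a -log10 one-sided binomial tail against a background sequence set

Enrichment probabilities are fractions of gold-standard pairs, and label
pairs are directional (E3 side vs substrate side are distinct axes).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import MotifParams
from .core_io import AMINO_ACIDS, AnnotationMap, ESIPair, PPINetwork, OrthologMap


class UndefinedRatioError(ValueError):
    """An enrichment ratio was requested for a label absent from its side."""


# ---------------------------------------------------------------------------
# annotation-pair enrichment (domain / GO)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class EnrichmentFeature:
    """A directional (E3-side, substrate-side) label pair with its ratio."""

    label_e3: str
    label_sub: str
    ratio: float
    support: int

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def _pair_label_counts(
    gsp: Iterable[ESIPair], ann: AnnotationMap
) -> tuple[int, Counter, Counter, Counter]:
    """Counts of gold pairs carrying each E3-side label, substrate-side label
    and ordered label pair.  Labels are counted once per pair (set semantics).
    """
    n_pairs = 0
    e3_marginal: Counter = Counter()
    sub_marginal: Counter = Counter()
    joint: Counter = Counter()
    for pair in gsp:
        n_pairs += 1
        e3_labels = ann.labels(pair.e3)
        sub_labels = ann.labels(pair.substrate)
        e3_marginal.update(e3_labels)
        sub_marginal.update(sub_labels)
        for le in e3_labels:
            for ls in sub_labels:
                joint[(le, ls)] += 1
    return n_pairs, e3_marginal, sub_marginal, joint


def pair_enrichment_ratio(
    label_e3: str,
    label_sub: str,
    gsp: Iterable[ESIPair],
    ann: AnnotationMap,
) -> float:
    """Enrichment ratio of an ordered label pair among gold-standard pairs.

    ``Pr(pair) / (Pr(label_e3 on E3 side) * Pr(label_sub on substrate side))``
    where each probability is a fraction of gold pairs.  Raises
    :class:`UndefinedRatioError` if either label never occurs on its side.
    """
    n, e3_marg, sub_marg, joint = _pair_label_counts(gsp, ann)
    if n == 0:
        raise ValueError("empty gold-standard positive set")
    if e3_marg[label_e3] == 0:
        raise UndefinedRatioError(f"label {label_e3!r} absent from E3 side")
    if sub_marg[label_sub] == 0:
        raise UndefinedRatioError(f"label {label_sub!r} absent from substrate side")
    return joint[(label_e3, label_sub)] * n / (e3_marg[label_e3] * sub_marg[label_sub])


def enriched_pair_table(
    gsp: Iterable[ESIPair],
    ann: AnnotationMap,
    min_ratio: float = 1.0,
    exclude_labels: frozenset[str] = frozenset(),
    min_support: int = 1,
) -> dict[tuple[str, str], EnrichmentFeature]:
    """All co-occurring ordered label pairs with ratio >= ``min_ratio``.

    Only pairs observed in at least one gold pair are considered (support >= 1
    by construction); ``min_support`` raises that floor, which suppresses the
    singleton co-occurrences whose ratio is always ~|GSP| regardless of any
    real association.  ``exclude_labels`` removes uninformative labels (e.g.
    GO root terms) from both sides.
    """
    gsp = list(gsp)
    if not gsp:
        raise ValueError("empty gold-standard positive set")
    n, e3_marg, sub_marg, joint = _pair_label_counts(gsp, ann)
    table: dict[tuple[str, str], EnrichmentFeature] = {}
    for (le, ls), support in joint.items():
        if support < min_support or le in exclude_labels or ls in exclude_labels:
            continue
        ratio = support * n / (e3_marg[le] * sub_marg[ls])
        if ratio >= min_ratio:
            table[(le, ls)] = EnrichmentFeature(le, ls, ratio, support)
    return table


def match_enrichment(
    pair: ESIPair,
    table: Mapping[tuple[str, str], EnrichmentFeature],
    ann: AnnotationMap,
) -> list[EnrichmentFeature]:
    """All table entries matching the pair's annotations (may be empty)."""
    hits = []
    for le in ann.labels(pair.e3):
        for ls in ann.labels(pair.substrate):
            feat = table.get((le, ls))
            if feat is not None:
                hits.append(feat)
    return hits


# ---------------------------------------------------------------------------
# ortholog transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class HomologyEvidence:
    supported: bool
    source_pair: ESIPair | None = None

    def __post_init__(self) -> None:
        if self.supported != (self.source_pair is not None):
            raise ValueError("supported=True iff a source pair is present")


def homology_support(
    pair: ESIPair,
    mouse_esis: Iterable[ESIPair],
    omap: OrthologMap,
) -> HomologyEvidence:
    """True iff some source-species pair maps onto this pair via the ortholog
    map (E3 to E3, substrate to substrate)."""
    for mpair in sorted(mouse_esis):
        if pair.e3 in omap.orthologs(mpair.e3) and pair.substrate in omap.orthologs(
            mpair.substrate
        ):
            return HomologyEvidence(True, mpair)
    return HomologyEvidence(False)


# ---------------------------------------------------------------------------
# network loops
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class LoopCounts:
    n3: int
    n4: int

    def __post_init__(self) -> None:
        if self.n3 < 0 or self.n4 < 0:
            raise ValueError("loop counts must be >= 0")


def count_loops(pair: ESIPair, ppi: PPINetwork) -> LoopCounts:
    """Triangles and 4-cycles through the query edge in ``ppi + query edge``.

    n3 = common neighbors of the endpoints (excluding the endpoints).
    n4 = pairs (x, y) with x adjacent to the E3, y adjacent to the substrate,
    x != y, x != substrate, y != e3, and (x, y) an edge; each 4-cycle through
    the query edge is counted exactly once (chords permitted).
    """
    e3, sub = pair.e3, pair.substrate
    nb_e3 = ppi.neighbors(e3) - {e3, sub}
    nb_sub = ppi.neighbors(sub) - {e3, sub}
    n3 = len(nb_e3 & nb_sub)
    n4 = 0
    for x in nb_e3:
        for y in ppi.neighbors(x):
            if y != x and y != e3 and y != sub and y in nb_sub:
                n4 += 1
    return LoopCounts(n3, n4)


# ---------------------------------------------------------------------------
# linear-motif discovery and matching
# ---------------------------------------------------------------------------

WILDCARD = "x"


@dataclass(frozen=True)
class Motif:
    """Ungapped consensus pattern tied to one E3.

    ``pattern`` holds one frozenset of residues per position; a wildcard
    position is the full residue set and renders as ``x``.
    """

    e3: str
    pattern: tuple[frozenset[str], ...]
    motif_score: float
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.fg_hits <= self.fg_total):
            raise ValueError("fg_hits must lie in [0, fg_total]")
        if not (0 <= self.bg_hits <= self.bg_total):
            raise ValueError("bg_hits must lie in [0, bg_total]")
        if self.motif_score < 0:
            raise ValueError("motif_score must be >= 0")

    @property
    def width(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return pattern_to_string(self.pattern)


_FULL = frozenset(AMINO_ACIDS)


def pattern_to_string(pattern: Sequence[frozenset[str]]) -> str:
    parts = []
    for pos in pattern:
        if pos >= _FULL:
            parts.append(WILDCARD)
        elif len(pos) == 1:
            parts.append(next(iter(pos)))
        else:
            parts.append("[" + "".join(sorted(pos)) + "]")
    return "".join(parts)


def pattern_from_string(text: str) -> tuple[frozenset[str], ...]:
    pattern: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == WILDCARD:
            pattern.append(_FULL)
            i += 1
        elif c == "[":
            j = text.index("]", i)
            pattern.append(frozenset(text[i + 1 : j]))
            i = j + 1
        else:
            pattern.append(frozenset(c))
            i += 1
    return tuple(pattern)


def match_motif(sequence: str, motif: Motif) -> bool:
    """True iff some window of the sequence satisfies every fixed position."""
    if not sequence:
        raise ValueError("empty sequence")
    return _contains(sequence, motif.pattern)


def _contains(sequence: str, pattern: Sequence[frozenset[str]]) -> bool:
    w = len(pattern)
    fixed = [(j, pos) for j, pos in enumerate(pattern) if not pos >= _FULL]
    for i in range(len(sequence) - w + 1):
        if all(sequence[i + j] in pos for j, pos in fixed):
            return True
    return False


def _binomial_score(
    fg_hits: int, fg_total: int, bg_hits: int, bg_total: int, p_floor: float
) -> float:
    """-log10 of the one-sided binomial tail P(X >= fg_hits | fg_total, p)."""
    p = max(bg_hits / bg_total, p_floor)
    p = min(p, 1.0)
    tail = stats.binom.sf(fg_hits - 1, fg_total, p)
    if tail <= 0.0:
        tail = 5e-324
    return float(-math.log10(tail))


def _hit_count(seqs: Sequence[str], pattern: Sequence[frozenset[str]]) -> int:
    return sum(1 for s in seqs if _contains(s, pattern))


_RES_INDEX = {res: i for i, res in enumerate(AMINO_ACIDS)}
_N_RES = len(AMINO_ACIDS)


def _window_matrices(seqs: Sequence[str], width: int) -> list[np.ndarray]:
    """Per sequence: (n_windows, width) residue-index matrix (X encoded as
    ``_N_RES`` so it never matches a fixed residue)."""
    mats = []
    for s in seqs:
        codes = np.fromiter(
            (_RES_INDEX.get(c, _N_RES) for c in s), dtype=np.int8, count=len(s)
        )
        if len(s) < width:
            mats.append(np.empty((0, width), dtype=np.int8))
        else:
            mats.append(np.lib.stride_tricks.sliding_window_view(codes, width))
    return mats


def _presence_counts(
    mats: Sequence[np.ndarray], alive: Sequence[np.ndarray], width: int
) -> np.ndarray:
    """counts[pos, res] = number of sequences with a live window carrying
    ``res`` at ``pos``."""
    counts = np.zeros((width, _N_RES), dtype=np.int64)
    for mat, mask in zip(mats, alive):
        if not mask.any():
            continue
        live = mat[mask]
        for pos in range(width):
            present = np.bincount(live[:, pos], minlength=_N_RES + 1)[:_N_RES] > 0
            counts[pos] += present
    return counts


def _greedy_search(
    fg: Sequence[str],
    bg: Sequence[str],
    width: int,
    params: MotifParams,
    p_floor: float,
) -> tuple[tuple[frozenset[str], ...], float, int, int] | None:
    """Greedily fix (position, residue) choices for one width.

    At each step every unfixed (position, residue) refinement is scored by the
    binomial enrichment of presence-in-sequence counts over the windows still
    compatible with the current pattern; the best strictly improving
    refinement is kept, ties broken by lexicographic (position, residue)
    order.  Returns (pattern, score, fg_hits, bg_hits), or None if nothing
    was fixed.
    """
    fg_mats = _window_matrices(fg, width)
    bg_mats = _window_matrices(bg, width)
    min_hits = max(params.min_fg_hits, math.ceil(params.min_fg_frac * len(fg)))

    def score_matrix(fg_alive, bg_alive, unfixed):
        fg_counts = _presence_counts(fg_mats, fg_alive, width)
        bg_counts = _presence_counts(bg_mats, bg_alive, width)
        p = np.maximum(bg_counts / max(len(bg), 1), p_floor).clip(max=1.0)
        with np.errstate(divide="ignore"):
            tails = stats.binom.sf(fg_counts - 1, len(fg), p)
            scores = -np.log10(np.maximum(tails, 5e-324))
        scores[fg_counts < min_hits] = -np.inf
        for pos in range(width):
            if pos not in unfixed:
                scores[pos, :] = -np.inf
        return scores, fg_counts, bg_counts

    def run_from(first: tuple[int, int]):
        """Deterministic greedy continuation after fixing ``first``."""
        fg_alive = [np.ones(len(m), dtype=bool) for m in fg_mats]
        bg_alive = [np.ones(len(m), dtype=bool) for m in bg_mats]
        pattern: list[frozenset[str]] = [_FULL] * width
        unfixed = set(range(width))
        best_score = 0.0
        counts = (0, 0)
        nxt: tuple[int, int] | None = first
        while unfixed:
            scores, fg_counts, bg_counts = score_matrix(fg_alive, bg_alive, unfixed)
            if nxt is None:
                flat = int(np.argmax(scores))  # first max in (pos, residue) order
                pos, res_i = divmod(flat, _N_RES)
            else:
                pos, res_i = nxt
            score = float(scores[pos, res_i])
            new_counts = (int(fg_counts[pos, res_i]), int(bg_counts[pos, res_i]))
            # strict improvement always; an equal score is accepted only when
            # it leaves the hit counts untouched, which extends a partial
            # pattern to the full consensus (e.g. x-E-N -> K-E-N) without
            # chasing noise
            improves = score > best_score
            extends = (
                nxt is None and score == best_score and new_counts == counts
            )
            if not np.isfinite(score) or not (improves or extends):
                break
            pattern[pos] = frozenset(AMINO_ACIDS[res_i])
            unfixed.discard(pos)
            for mat, mask in zip(fg_mats, fg_alive):
                if len(mat):
                    mask &= mat[:, pos] == res_i
            for mat, mask in zip(bg_mats, bg_alive):
                if len(mat):
                    mask &= mat[:, pos] == res_i
            best_score = score
            counts = new_counts
            nxt = None
        n_fixed = width - len(unfixed)
        return pattern, best_score, counts, n_fixed

    # the first fixed choice often ties across shifted variants of the same
    # planted word (K@0 vs E@1 vs N@2 for KEN); branch over the tied top
    # candidates and keep the continuation fixing the most positions
    all_alive = [np.ones(len(m), dtype=bool) for m in fg_mats]
    all_alive_bg = [np.ones(len(m), dtype=bool) for m in bg_mats]
    first_scores, _, _ = score_matrix(all_alive, all_alive_bg, set(range(width)))
    top = float(np.max(first_scores))
    if not np.isfinite(top) or top <= 0.0:
        return None
    tied = [
        (int(i) // _N_RES, int(i) % _N_RES)
        for i in np.flatnonzero(first_scores == top)[:24]
    ]
    best = None
    for cand in tied:
        pattern, score, counts, n_fixed = run_from(cand)
        if n_fixed == 0:
            continue
        key = (-score, -n_fixed, pattern_to_string(pattern))
        if best is None or key < best[0]:
            best = (key, pattern, score, counts)
    if best is None:
        return None
    _, pattern, score, counts = best
    return tuple(pattern), score, counts[0], counts[1]


def _best_exact_word(
    fg: Sequence[str],
    bg: Sequence[str],
    width: int,
    min_hits: int,
    p_floor: float,
) -> tuple[tuple[frozenset[str], ...], float, int, int] | None:
    """Best fully-fixed w-mer among those present in >= min_hits foreground
    sequences.  Complements the greedy search, whose first residue-marginal
    step can walk past an exact planted word."""
    word_counts: Counter = Counter()
    for s in fg:
        word_counts.update(
            {s[i : i + width] for i in range(len(s) - width + 1)}
        )
    best: tuple[float, str, int, int] | None = None  # (-score, word, fgh, bgh)
    for word, fg_hits in word_counts.items():
        if fg_hits < min_hits or "X" in word:
            continue
        bg_hits = sum(1 for s in bg if word in s)
        score = _binomial_score(fg_hits, len(fg), bg_hits, len(bg), p_floor)
        cand = (-score, word, fg_hits, bg_hits)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_score, word, fg_hits, bg_hits = best
    pattern = tuple(frozenset(c) for c in word)
    return pattern, -neg_score, fg_hits, bg_hits


def _n_fixed(pattern: Sequence[frozenset[str]]) -> int:
    return sum(1 for pos in pattern if not pos >= _FULL)


def discover_motifs(
    e3: str,
    foreground: Mapping[str, str],
    background: Mapping[str, str],
    params: MotifParams | None = None,
) -> list[Motif]:
    """Iteratively extract enriched ungapped motifs for one E3.

    ``foreground`` holds the E3's known substrate sequences, ``background``
    the sequences of its generic interactors.  Per width, both the greedy
    position-refinement search and an exact-word scan propose a candidate;
    the best candidate overall is emitted when its score clears
    ``params.score_threshold``, sequences matching it are removed, and the
    search repeats.
    """
    params = params or MotifParams()
    if not background:
        raise ValueError("empty background sequence set")
    fg = [foreground[k] for k in sorted(foreground)]
    bg = [background[k] for k in sorted(background)]
    p_floor = params.p_floor if params.p_floor is not None else 1.0 / (len(bg) + 1)
    motifs: list[Motif] = []
    while len(fg) >= params.min_fg and len(motifs) < params.max_motifs_per_e3:
        min_hits = max(params.min_fg_hits, math.ceil(params.min_fg_frac * len(fg)))
        candidates = []
        for width in params.widths:
            proposals = [
                _greedy_search(fg, bg, width, params, p_floor),
                _best_exact_word(fg, bg, width, min_hits, p_floor),
            ]
            for hit in proposals:
                if hit is None:
                    continue
                pattern, score, fg_hits, bg_hits = hit
                if _n_fixed(pattern) < params.min_fixed_positions:
                    continue
                candidates.append(
                    (-score, width, pattern_to_string(pattern), pattern,
                     fg_hits, bg_hits)
                )
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        neg_score, _w, _s, pattern, fg_hits, bg_hits = candidates[0]
        score = -neg_score
        if score <= params.score_threshold:
            break
        motifs.append(
            Motif(e3, pattern, score, fg_hits, len(fg), bg_hits, len(bg))
        )
        fg = [s for s in fg if not _contains(s, pattern)]
    return motifs
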
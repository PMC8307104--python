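"""Template-constrained cloverleaf folding for mitochondrial tRNAs.

Mitochondrial tRNA genes (63-71 bp in the grasshopper fixtures) fold into the
canonical cloverleaf: a 7-bp acceptor stem, a DHU arm (2-4 bp stem, absent in
trnS(AGN)), an anticodon arm (3-6 bp stem with a 7-nt loop holding the
anticodon at its center), a variable loop, and a TpsiC arm (3-6 bp stem).
Rather than free-energy minimisation, this module anchors the anticodon loop
at the annotated anticodon and exhaustively searches arm-length combinations
inside those template bounds, scoring

    +2 per Watson-Crick pair, +1 per G.U wobble, -1 per retained mismatch

and keeping the best-scoring decomposition. Mismatches (U-U, U-C, A-A, A-G,
A-C and the like) are retained in stems, matching what is observed in real
mitochondrial tRNAs. Ties break deterministically: higher acceptor-stem
score, then the canonical DHU stem of 4 bp, then a canonical variable loop of
4-5 nt, then first in enumeration order.

The same template drives the sequence designer used by the synthetic-data
generator: it emits sequences with perfect Watson-Crick stems whose fold is
recoverable by :func:`fold_trna`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import AnchorError, FoldFailureError, StructureError, TooShortError

PAIR_SCORE = {
    ("A", "T"): 2, ("T", "A"): 2, ("G", "C"): 2, ("C", "G"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class TemplateBounds:
    """Search bounds for each cloverleaf element (nt)."""

    acceptor_stem: int = 7
    conn1: tuple[int, int] = (0, 3)          # acceptor -> DHU connector
    dhu_stem: tuple[int, ...] = (0, 2, 3, 4)  # 0 = DHU arm absent
    dhu_loop: tuple[int, int] = (3, 11)
    dhu_region: tuple[int, int] = (2, 12)     # unpaired span when arm absent
    conn2: tuple[int, int] = (0, 2)           # DHU -> anticodon connector
    anticodon_stem: tuple[int, int] = (3, 6)
    anticodon_loop: int = 7
    variable_loop: tuple[int, int] = (3, 9)
    t_stem: tuple[int, int] = (3, 6)
    t_loop: tuple[int, int] = (3, 9)
    trail: tuple[int, int] = (0, 3)           # unpaired 3' tail (discriminator)


DEFAULT_BOUNDS = TemplateBounds()


@dataclass(frozen=True)
class CloverleafStructure:
    """Arm-resolved decomposition of a tRNA sequence.

    ``segments`` maps element name -> half-open (start, end) index span; the
    spans partition ``range(length)``. Pair lists hold (5', 3') index tuples.
    """

    length: int
    segments: dict[str, tuple[int, int]]
    acceptor_pairs: tuple[tuple[int, int], ...]
    dhu_pairs: tuple[tuple[int, int], ...]
    anticodon_pairs: tuple[tuple[int, int], ...]
    t_pairs: tuple[tuple[int, int], ...]
    anticodon_index: int  # 0-based index of the anticodon's first base
    score: int

    @property
    def dhu_present(self) -> bool:
        return len(self.dhu_pairs) > 0

    @property
    def arm_lengths(self) -> dict[str, int]:
        return {
            "acceptor": len(self.acceptor_pairs),
            "dhu": len(self.dhu_pairs),
            "anticodon": len(self.anticodon_pairs),
            "t": len(self.t_pairs),
            "variable_loop": self.segments["variable_loop"][1]
            - self.segments["variable_loop"][0],
        }

    @property
    def all_pairs(self) -> tuple[tuple[int, int], ...]:
        return (
            self.acceptor_pairs + self.dhu_pairs
            + self.anticodon_pairs + self.t_pairs
        )

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.all_pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


@dataclass(frozen=True)
class PairClassification:
    watson_crick: int
    gu_wobble: int
    mismatches: tuple[tuple[tuple[int, int], str], ...]

    @property
    def total(self) -> int:
        return self.watson_crick + self.gu_wobble + len(self.mismatches)


def _stem_score(seq: str, i5: int, j3: int, n: int) -> int:
    """Score n pairs between seq[i5:i5+n] and the reversed seq[j3:j3+n]."""
    score = 0
    for k in range(n):
        score += PAIR_SCORE.get((seq[i5 + k], seq[j3 + n - 1 - k]), -1)
    return score


def _stem_pairs(i5: int, j3: int, n: int) -> tuple[tuple[int, int], ...]:
    return tuple((i5 + k, j3 + n - 1 - k) for k in range(n))


def fold_trna(
    seq: str,
    anticodon: str,
    bounds: TemplateBounds = DEFAULT_BOUNDS,
    relax_anticodon_loop: bool = False,
) -> CloverleafStructure:
    """Fold a tRNA gene sequence into its best template-consistent cloverleaf.

    The anticodon anchors the anticodon loop (all occurrences are tried).
    ``relax_anticodon_loop`` additionally allows a 9-nt anticodon loop, the
    single known exception in the study fixtures.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if L < 50:
        raise TooShortError(f"{L} nt is too short for a tRNA (need >= 50)")
    if L > 100:
        raise TooShortError(f"{L} nt is too long for a tRNA (need <= 100)")
    anticodon = anticodon.upper().replace("U", "T")
    anchors = [i for i in range(L - 2) if seq[i : i + 3] == anticodon]
    if not anchors:
        raise AnchorError(f"anticodon {anticodon} not found in sequence")

    loop_lengths = (7, 9) if relax_anticodon_loop else (7,)
    acc = bounds.acceptor_stem
    best_key = None
    best: Optional[CloverleafStructure] = None

    # acceptor 3' strand position depends only on the trailing span
    trail_options = []
    for trail in range(bounds.trail[0], bounds.trail[1] + 1):
        j3 = L - trail - acc
        if j3 <= 0:
            continue
        trail_options.append((trail, j3, _stem_score(seq, 0, j3, acc)))

    for p0 in anchors:
        for al in loop_lengths:
            loop_start = p0 - 2 - (al - 7) // 2
            for a in range(bounds.anticodon_stem[0], bounds.anticodon_stem[1] + 1):
                ac5 = loop_start - a
                left_budget = ac5 - acc  # conn1 + dhu region + conn2
                if ac5 < 0 or left_budget < 0 or loop_start + al + a > L:
                    continue
                ac_score = _stem_score(seq, ac5, loop_start + al, a)
                left_combos = _left_combos(seq, acc, left_budget, bounds)
                if not left_combos:
                    continue
                right_start = loop_start + al + a
                right_combos = _right_combos(
                    seq, right_start, L, trail_options, bounds
                )
                for d_score, d, dloop, c1, c2 in left_combos:
                    for (t_acc_score, acc_score, t, tl, v, trail,
                         j3acc) in right_combos:
                        total = ac_score + d_score + t_acc_score
                        key = (
                            total,
                            acc_score,
                            1 if d == 4 else 0,
                            1 if v in (4, 5) else 0,
                        )
                        if best_key is not None and key <= best_key:
                            continue
                        best_key = key
                        best = _assemble(
                            seq, L, acc, c1, d, dloop, c2, a, al, v, t, tl,
                            trail, loop_start, p0, j3acc, right_start, total,
                        )
    if best is None:
        raise FoldFailureError(
            "no template-consistent cloverleaf decomposition found"
        )
    return best


def _left_combos(seq, acc, budget, bounds):
    """(score, d, dloop, conn1, conn2) choices filling the DHU region."""
    combos = []
    for d in sorted(bounds.dhu_stem):
        if d == 0:
            loop_lo, loop_hi = bounds.dhu_region
        else:
            loop_lo, loop_hi = bounds.dhu_loop
        for dloop in range(loop_lo, loop_hi + 1):
            rem = budget - (2 * d + dloop)
            for c2 in range(bounds.conn2[0], bounds.conn2[1] + 1):
                c1 = rem - c2
                if not (bounds.conn1[0] <= c1 <= bounds.conn1[1]):
                    continue
                d5 = acc + c1
                score = _stem_score(seq, d5, d5 + d + dloop, d) if d else 0
                combos.append((score, d, dloop, c1, c2))
    return combos


def _right_combos(seq, right_start, L, trail_options, bounds):
    """(t+acceptor score, acc score, t, tloop, v, trail, j3acc) choices."""
    combos = []
    for trail, j3acc, acc_score in trail_options:
        budget = j3acc - right_start  # v + 2t + tloop
        for t in range(bounds.t_stem[0], bounds.t_stem[1] + 1):
            for tl in range(bounds.t_loop[0], bounds.t_loop[1] + 1):
                v = budget - 2 * t - tl
                if not (bounds.variable_loop[0] <= v <= bounds.variable_loop[1]):
                    continue
                t5 = right_start + v
                t_score = _stem_score(seq, t5, t5 + t + tl, t)
                combos.append(
                    (t_score + acc_score, acc_score, t, tl, v, trail, j3acc)
                )
    return combos


def _assemble(seq, L, acc, c1, d, dloop, c2, a, al, v, t, tl, trail,
              loop_start, p0, j3acc, right_start, total) -> CloverleafStructure:
    segments: dict[str, tuple[int, int]] = {}
    pos = 0

    def put(name, n):
        nonlocal pos
        segments[name] = (pos, pos + n)
        pos += n

    put("acceptor_5", acc)
    put("conn1", c1)
    if d:
        put("dhu_5", d)
        put("dhu_loop", dloop)
        put("dhu_3", d)
    else:
        put("dhu_loop", dloop)
    put("conn2", c2)
    put("anticodon_5", a)
    put("anticodon_loop", al)
    put("anticodon_3", a)
    put("variable_loop", v)
    put("t_5", t)
    put("t_loop", tl)
    put("t_3", t)
    put("acceptor_3", acc)
    put("trail", trail)
    if pos != L:
        raise StructureError("segment decomposition does not tile the sequence")

    d5 = segments["dhu_5"][0] if d else 0
    t5 = segments["t_5"][0]
    return CloverleafStructure(
        length=L,
        segments=segments,
        acceptor_pairs=_stem_pairs(0, j3acc, acc),
        dhu_pairs=_stem_pairs(d5, d5 + d + dloop, d) if d else (),
        anticodon_pairs=_stem_pairs(loop_start - a, loop_start + al, a),
        t_pairs=_stem_pairs(t5, t5 + t + tl, t),
        anticodon_index=p0,
        score=total,
    )


def classify_pairs(structure: CloverleafStructure, seq: str) -> PairClassification:
    """Label every stem pair Watson-Crick, G.U wobble, or mismatch (by type)."""
    seq = seq.upper().replace("U", "T")
    wc = gu = 0
    mismatches = []
    for i, j in structure.all_pairs:
        if i >= len(seq) or j >= len(seq):
            raise StructureError(f"pair ({i},{j}) outside sequence of {len(seq)}")
        pair = (seq[i], seq[j])
        if pair in WATSON_CRICK:
            wc += 1
        elif pair in WOBBLE:
            gu += 1
        else:
            label = "-".join(b.replace("T", "U") for b in pair)
            mismatches.append(((i, j), label))
    return PairClassification(
        watson_crick=wc, gu_wobble=gu, mismatches=tuple(mismatches)
    )


def compare_structures(
    folds: Mapping[str, tuple[CloverleafStructure, str]],
    reference: str,
) -> list[str]:
    """Per-position conservation labels for the reference species' tRNA.

    Positions are compared arm-relative (same element, same offset within the
    element), not by raw index, so length variation in loops does not smear
    the comparison. A reference position is 'conserved' when every species
    has the identical nucleotide at the homologous element offset, otherwise
    'variable'.
    """
    if reference not in folds:
        raise KeyError(reference)

    def coordinate_map(structure, seq):
        seq = seq.upper().replace("U", "T")
        coords = {}
        for name, (lo, hi) in structure.segments.items():
            for off, idx in enumerate(range(lo, hi)):
                coords[(name, off)] = seq[idx]
        return coords

    maps = {sp: coordinate_map(st, sq) for sp, (st, sq) in folds.items()}
    ref_structure, ref_seq = folds[reference]
    labels = ["variable"] * ref_structure.length
    for name, (lo, hi) in ref_structure.segments.items():
        for off, idx in enumerate(range(lo, hi)):
            base = maps[reference][(name, off)]
            conserved = all(
                m.get((name, off)) == base for m in maps.values()
            )
            labels[idx] = "conserved" if conserved else "variable"
    return labels


# ---------------------------------------------------------------------------
# Template-consistent sequence design (used by the synthetic-data generator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaDesign:
    """Element lengths for a designed template-consistent tRNA."""

    conn1: int = 2
    dhu_stem: int = 4
    dhu_loop: int = 7
    conn2: int = 1
    anticodon_stem: int = 5
    variable_loop: int = 4
    t_stem: int = 5
    t_loop: int = 7
    trail: int = 0
    anticodon_loop: int = 7

    @property
    def total_length(self) -> int:
        return (
            14 + self.conn1 + 2 * self.dhu_stem + self.dhu_loop + self.conn2
            + 2 * self.anticodon_stem + self.anticodon_loop
            + self.variable_loop + 2 * self.t_stem + self.t_loop + self.trail
        )


_WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G"}


def design_trna(
    rng: np.random.Generator,
    anticodon: str,
    design: TrnaDesign = TrnaDesign(),
) -> str:
    """Generate a random sequence realizing ``design`` with perfect WC stems.

    The realization is built to make the designed decomposition the strict
    score optimum, so :func:`fold_trna` can recover the generating arm
    lengths: stems use G-C pairs only (random G/C 5' strands, complemented
    3' strands) and every unpaired span is adenine. A alone never pairs, and
    the only T/G outside stems is the planted anticodon, which no candidate
    stem can reach - so any alternative arm-length assignment must pair
    through an A and scores strictly worse. The acceptor 5' strand is redrawn
    until aperiodic (no period 1-3), which rules out score-tied shifted
    acceptor windows.
    """
    anticodon = anticodon.upper().replace("U", "T")
    d = design
    L = d.total_length
    seq = ["A"] * L
    pos = 0
    spans = {}

    def put(name, n):
        nonlocal pos
        spans[name] = (pos, pos + n)
        pos += n

    put("acceptor_5", 7)
    put("conn1", d.conn1)
    if d.dhu_stem:
        put("dhu_5", d.dhu_stem)
        put("dhu_loop", d.dhu_loop)
        put("dhu_3", d.dhu_stem)
    else:
        put("dhu_loop", d.dhu_loop)
    put("conn2", d.conn2)
    put("anticodon_5", d.anticodon_stem)
    put("anticodon_loop", d.anticodon_loop)
    put("anticodon_3", d.anticodon_stem)
    put("variable_loop", d.variable_loop)
    put("t_5", d.t_stem)
    put("t_loop", d.t_loop)
    put("t_3", d.t_stem)
    put("acceptor_3", 7)
    put("trail", d.trail)
    assert pos == L

    def gc_strand(n, aperiodic=False):
        while True:
            strand = [("G", "C")[int(b)] for b in rng.integers(0, 2, size=n)]
            if not aperiodic:
                return strand
            if all(
                any(strand[k] != strand[k + s] for k in range(n - s))
                for s in (1, 2, 3)
            ):
                return strand

    stems = [("acceptor_5", "acceptor_3", True)]
    if d.dhu_stem:
        stems.append(("dhu_5", "dhu_3", False))
    stems.append(("anticodon_5", "anticodon_3", False))
    stems.append(("t_5", "t_3", False))
    for five, three, aperiodic in stems:
        lo5, hi5 = spans[five]
        lo3, _ = spans[three]
        n = hi5 - lo5
        strand = gc_strand(n, aperiodic=aperiodic)
        for k in range(n):
            seq[lo5 + k] = strand[k]
            seq[lo3 + n - 1 - k] = _WC_PARTNER[strand[k]]

    # plant the anticodon at the loop center
    lo, hi = spans["anticodon_loop"]
    ac_start = lo + 2 + ((hi - lo) - 7) // 2
    seq[ac_start : ac_start + 3] = list(anticodon)
    return "".join(seq)
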
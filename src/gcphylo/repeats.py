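"""Maximal exact repeat detection in genome sequences.

Finds all maximal exact repeat pairs of four kinds — forward, reverse,
complement and reverse-complement — above a minimum length, in the style
of classic repeat finders for organellar genomes.  A hit is a pair of
substrings that match under the kind's transform and cannot be extended
by one base on either side without breaking the match.

Detection is seed-and-extend on exact k-mers (k = min_len): every
maximal match of length >= min_len contains at least one aligned seed,
and extension from any of its seeds reconstructs the same maximal pair,
so enumeration is exact.  Output order is deterministic
(start1, start2, kind).
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGT", "TGCA")
KINDS = ("forward", "reverse", "complement", "reverse_complement")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _transform(seq: str, kind: str) -> str:
    if kind == "forward":
        return seq
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return seq.translate(COMPLEMENT)
    if kind == "reverse_complement":
        return revcomp(seq)
    raise ValueError(f"unknown repeat kind {kind!r}; expected one of {KINDS}")


@dataclass(frozen=True, order=True)
class RepeatHit:
    """One maximal repeat pair; coordinates are 1-based inclusive on the
    original sequence, giving the left ends of both copies."""

    start1: int
    start2: int
    length: int
    kind: str


def _maximal_pairs(s: str, t: str, min_len: int, self_forward: bool) -> set[tuple[int, int, int]]:
    """Maximal common-substring pairs (i, j, L) between s and t, 0-based.

    When `self_forward`, s is t and the trivial i == j diagonal is
    excluded (and symmetric pairs deduplicated to i < j).
    """
    n, m = len(s), len(t)
    seeds: dict[str, list[int]] = {}
    for j in range(m - min_len + 1):
        seeds.setdefault(t[j : j + min_len], []).append(j)
    out: set[tuple[int, int, int]] = set()
    seen_diag: set[tuple[int, int]] = set()  # (j - i, i) canonical left end
    for i in range(n - min_len + 1):
        for j in seeds.get(s[i : i + min_len], ()):
            if self_forward and i == j:
                continue
            # extend left
            a, b = i, j
            while a > 0 and b > 0 and s[a - 1] == t[b - 1]:
                a -= 1
                b -= 1
            if (b - a, a) in seen_diag:
                continue
            seen_diag.add((b - a, a))
            # extend right
            ea, eb = i + min_len, j + min_len
            while ea < n and eb < m and s[ea] == t[eb]:
                ea += 1
                eb += 1
            length = ea - a
            if length < min_len or (self_forward and a == b):
                continue
            if self_forward and a > b:
                a, b = b, a
            out.add((a, b, length))
    return out


def find_maximal_repeats(
    seq: str, min_len: int = 20, kinds: tuple[str, ...] = KINDS
) -> list[RepeatHit]:
    """All maximal exact repeat pairs of each requested kind in `seq`.

    For the non-forward kinds, hits are maximal common substrings between
    the sequence and its transform, with both coordinates mapped back to
    the original strand (left end of each copy, 1-based).  A palindromic
    site (its own reverse complement) is reported once.
    """
    if min_len < 2:
        raise ValueError("min_len must be at least 2")
    seq = seq.upper()
    n = len(seq)
    hits: list[RepeatHit] = []
    for kind in kinds:
        if kind not in KINDS:
            raise ValueError(f"unknown repeat kind {kind!r}")
        t = _transform(seq, kind)
        pairs = _maximal_pairs(seq, t, min_len, self_forward=(kind == "forward"))
        for a, b, length in pairs:
            # map t-coordinates back to the original sequence
            if kind in ("reverse", "reverse_complement"):
                b_orig = n - (b + length)  # left end after un-reversing
            else:
                b_orig = b
            s1, s2 = a, b_orig
            if kind != "forward" and (s2, length) < (s1, length):
                s1, s2 = s2, s1  # canonical order; the pair is symmetric
            hits.append(RepeatHit(s1 + 1, s2 + 1, length, kind))
    # reversal-symmetric kinds report each pair twice; dedupe keeps one
    uniq = sorted(
        set(hits), key=lambda h: (h.start1, h.start2, KINDS.index(h.kind), h.length)
    )
    return uniq


def repeat_stats(hits: list[RepeatHit], seq: str) -> tuple[int, int, float | None]:
    """(NRS, RSL, GC within repeats) for a set of hits on `seq`.

    NRS counts maximal repeat pairs.  RSL is the length of the per-base
    union of all copies, so overlapping and nested hits are not double
    counted.  GC-in-repeats is the GC fraction over that union (None
    when there are no hits).
    """
    if not hits:
        return 0, 0, None
    n = len(seq)
    covered: set[int] = set()
    for h in hits:
        # modulo handles hits that span the origin of a circular genome
        covered.update(i % n for i in range(h.start1 - 1, h.start1 - 1 + h.length))
        covered.update(i % n for i in range(h.start2 - 1, h.start2 - 1 + h.length))
    bases = [seq[i].upper() for i in sorted(covered)]
    acgt = [b for b in bases if b in "ACGT"]
    gc = sum(b in "GC" for b in acgt) / len(acgt) if acgt else None
    return len(hits), len(covered), gc
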
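"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, without
sharing matching or search code with the library implementations.
"""

from __future__ import annotations

import itertools

from slrpev.motif import (
    AMINO_ACIDS,
    Exclusion,
    Fixed,
    PrositePattern,
    ResidueClass,
    Wildcard,
)
from slrpev.cluster_evolution import (
    HistoryTree,
    Scenario,
    TandemDup,
    replay,
)


def _accepts(element, ch: str) -> bool:
    if ch not in AMINO_ACIDS:
        return False
    if isinstance(element, Fixed):
        return ch == element.residue
    if isinstance(element, ResidueClass):
        return ch in element.residues
    if isinstance(element, Exclusion):
        return ch not in element.residues
    raise TypeError(element)


def brute_force_matches(pattern: PrositePattern, seq: str) -> dict[int, set[int]]:
    """All (start -> set of exclusive ends) full matches, by pure enumeration."""
    seq = seq.upper()
    star = seq.find("*")
    if star >= 0:
        seq = seq[:star]
    elements = pattern.elements

    def all_ends(i: int, pos: int) -> set[int]:
        if i == len(elements):
            return {pos}
        el = elements[i]
        out: set[int] = set()
        if isinstance(el, Wildcard):
            for k in range(el.min_repeat, el.max_repeat + 1):
                if pos + k <= len(seq):
                    out |= all_ends(i + 1, pos + k)
        elif pos < len(seq) and _accepts(el, seq[pos]):
            out |= all_ends(i + 1, pos + 1)
        return out

    result = {}
    for start in range(len(seq)):
        ends = all_ends(0, start)
        if ends:
            result[start] = ends
    return result


def brute_force_hits(pattern: PrositePattern, seq: str) -> list[tuple[int, int]]:
    """Expected scan() output: (1-based start, 1-based inclusive shortest end)."""
    return [
        (start + 1, min(ends))
        for start, ends in sorted(brute_force_matches(pattern, seq).items())
    ]


def oracle_min_dups(counts: dict[str, int], history: HistoryTree) -> int:
    """Minimal duplications by replaying every placement (losses free)."""
    branches = history.branches
    upper = sum(max(0, c - 1) for c in counts.values())
    for d in range(upper + 1):
        for placement in itertools.combinations_with_replacement(branches, d):
            scenario = Scenario(
                root_composition=(("3", "L1"),),
                events=tuple(
                    TandemDup(b, "L1", f"N{i}") for i, b in enumerate(placement)
                ),
            )
            comp = replay(scenario, history)
            if all(
                len(comp[tip]) >= counts.get(tip, 0) for tip in history.tips
            ):
                return d
    return upper
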
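"""Compact letter display for pairwise significance matrices.

Implements the insert-and-absorb algorithm: start from one group holding all
treatments; for every significantly different pair split any group that
contains both; absorb groups that are subsets of others; assign letters in
label order. Two treatments share a letter iff they are not significantly
different.
"""

from __future__ import annotations

import string


def compact_letter_display(labels: list[str], p_values: dict[tuple[str, str], float],
                           alpha: float = 0.05) -> dict[str, str]:
    """Letters per label from a pairwise p-value map (unordered pairs)."""

    def p_of(a: str, b: str) -> float:
        if (a, b) in p_values:
            return p_values[(a, b)]
        if (b, a) in p_values:
            return p_values[(b, a)]
        raise KeyError(f"missing p-value for pair ({a}, {b})")

    groups: list[set[str]] = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if p_of(a, b) >= alpha:
                continue
            new_groups: list[set[str]] = []
            for grp in groups:
                if a in grp and b in grp:
                    new_groups.append(grp - {a})
                    new_groups.append(grp - {b})
                else:
                    new_groups.append(grp)
            # absorb: drop groups contained in another
            groups = [g for g in new_groups if g and not any(
                g < h for h in new_groups)]
            # dedupe while keeping order
            seen: list[set[str]] = []
            for g in groups:
                if g not in seen:
                    seen.append(g)
            groups = seen
    # letters ordered by the first (in label order) member of each group
    order = {lab: i for i, lab in enumerate(labels)}
    groups.sort(key=lambda g: min(order[x] for x in g))
    letters = {lab: "" for lab in labels}
    for letter, grp in zip(string.ascii_lowercase, groups):
        for lab in labels:
            if lab in grp:
                letters[lab] += letter
    return letters
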
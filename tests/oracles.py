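"""Independent brute-force oracles for voucher selection and consensus naming."""

from collections import Counter

UNIDENTIFIED = "UNIDENTIFIED"


def brute_force_voucher(members):
    """members: list of (record_id, spatial_score, completeness_score).

    Full scan: highest total, ties by higher completeness, then smallest id.
    """
    ranked = sorted(members, key=lambda m: (-(m[1] + m[2]), -m[2], m[0]))
    return ranked[0][0]


def brute_force_consensus(names):
    """names: species-or-below determinations of the group (may be empty)."""
    if not names:
        return UNIDENTIFIED
    counts = Counter(names)
    top = max(counts.values())
    return min(n for n, c in counts.items() if c == top)
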
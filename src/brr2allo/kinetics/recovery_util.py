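"""Seed derivation for multi-seed simulation experiments."""

__all__ = ["derive_seed"]

_MERSENNE_31 = 2_147_483_647  # keeps derived seeds below 2**31


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-experiment seed from a base seed and an index."""
    return (base_seed * 1_000_003 + index * 7_919 + 1) % _MERSENNE_31
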
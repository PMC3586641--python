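"""Shared contract of all randomization tests.

Every permutation test in the package returns a :class:`PermutationResult`
carrying the observed statistic, the null replicates (or their range), the
one-tailed P value and the seed, so reports are fully reproducible.

Unless a test documents otherwise, P follows the add-one convention
P = (1 + #{extreme replicates}) / (1 + n_perm), which is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_permutations: int
    p_value: float
    tail: str  # "greater" or "less": direction counted as extreme
    seed: int | None = None
    null_replicates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"P value {self.p_value} outside (0, 1]")

    @property
    def null_range(self) -> tuple[float, float] | None:
        if self.null_replicates is None or len(self.null_replicates) == 0:
            return None
        return (float(np.min(self.null_replicates)),
                float(np.max(self.null_replicates)))

    def to_dict(self) -> dict:
        rng = self.null_range
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "tail": self.tail,
            "seed": self.seed,
            "null_min": None if rng is None else rng[0],
            "null_max": None if rng is None else rng[1],
        }


def add_one_pvalue(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """(1 + #{extreme}) / (1 + n): positively biased, never zero."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        b = int(np.sum(null >= observed))
    elif tail == "less":
        b = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + b) / (1 + null.size)
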
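"""Small statistics layer: group summaries, fold changes, organoid percent
survival, and Benjamini-Hochberg FDR adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GroupSummary", "fold_change", "percent_survival", "bh_adjust"]


@dataclass
class GroupSummary:
    """Mean +/- SEM summary of one experimental group."""

    label: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        n = values.size
        if n < 1:
            raise ValueError("group needs at least one value")
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return cls(label=label, n=n, mean=float(values.mean()), sem=sem)


def fold_change(experimental: GroupSummary, control: GroupSummary,
                direction: str) -> float:
    """Fold change between group means.

    ``increase``: experimental mean / control mean.
    ``decrease``: control mean / experimental mean.
    Both means must be positive.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")
    if experimental.mean <= 0 or control.mean <= 0:
        raise ValueError("fold change requires positive group means")
    if direction == "increase":
        return experimental.mean / control.mean
    return control.mean / experimental.mean


def percent_survival(pre_count: int, post_count: int) -> float:
    """Organoid percent survival: 100 * post-treatment / pre-treatment."""
    if pre_count < 1:
        raise ValueError("pre-treatment count must be >= 1")
    if post_count < 0:
        raise ValueError("post-treatment count must be >= 0")
    return 100.0 * post_count / pre_count


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original method).

    Sort ascending, take ``q(i) = min_{j >= i} p(j) * m / j`` capped at 1,
    and return in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
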
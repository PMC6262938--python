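"""Group coancestry and status effective population size.

The group coancestry of a sample of ``n`` individuals with inbreeding
coefficient ``F`` and pairwise coancestries ``theta_ij`` is

    Theta = [ 0.5 n (1 + F) + sum_i sum_{j != i} theta_ij ] / n^2,

the mean of all n^2 within- and between-individual coancestries (the double
sum runs over ordered pairs, so each unordered pair counts twice; with all
theta_ij = 0 and F = 0 this reduces to 1/(2n)).  Negative F estimates are
floored at zero.  The status effective size is ``Ne = 0.5 / Theta``: the size
of an ideal unrelated, non-inbred population with the same group coancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from palmflow.sgs import CoancestryMatrix


@dataclass
class GroupCoancestryResult:
    stage: str | None
    theta_group: float
    F_used: float
    n: int
    ne: float | None
    ratio: float | None  # Ne / n

    def __post_init__(self) -> None:
        if self.ne is not None and self.ne <= 0:
            raise ValueError("Ne must be positive when defined")


def ne_from_theta(theta_group: float) -> float:
    """Status effective size Ne = 0.5 / Theta."""
    if theta_group <= 0:
        raise ValueError("group coancestry must be positive for Ne")
    return 0.5 / theta_group


def group_coancestry(
    coancestry: CoancestryMatrix | np.ndarray,
    F: float,
    n: int | None = None,
    stage: str | None = None,
) -> GroupCoancestryResult:
    """Group coancestry Theta and effective size from a coancestry matrix.

    ``coancestry`` may be a CoancestryMatrix or a plain (n, n) array whose
    off-diagonal entries are theta_ij.  ``F`` is the (multilocus) fixation
    index of the same sample; negative values are treated as zero.
    """
    if isinstance(coancestry, CoancestryMatrix):
        theta = coancestry.theta
        stage = stage if stage is not None else coancestry.stage
    else:
        theta = np.asarray(coancestry, dtype=float)
    if n is None:
        n = theta.shape[0]
    if not np.isfinite(F):
        raise ValueError("F must be finite")
    off = theta.copy()
    np.fill_diagonal(off, 0.0)
    if np.isnan(off).any():
        raise ValueError("coancestry matrix has missing off-diagonal entries")
    F_used = max(float(F), 0.0)
    theta_group = (0.5 * n * (1.0 + F_used) + off.sum()) / n**2
    if theta_group <= 0:
        return GroupCoancestryResult(
            stage=stage, theta_group=theta_group, F_used=F_used, n=n,
            ne=None, ratio=None,
        )
    ne = ne_from_theta(theta_group)
    return GroupCoancestryResult(
        stage=stage,
        theta_group=theta_group,
        F_used=F_used,
        n=n,
        ne=ne,
        ratio=ne / n,
    )
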
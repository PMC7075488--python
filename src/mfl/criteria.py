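"""Closed-form distinctiveness criteria for multidimensional instruments.

Two latent variables X and Y are *distinct* under the Fornell-Larcker
criterion when each explains more variance in its own indicators than it
shares with the other::

    AVE_x > phi_xy**2   and   AVE_y > phi_xy**2

where AVE is the average variance extracted (mean squared standardized
loading) and phi_xy the latent correlation.  The *manifest* variant (mFL)
estimates both sides from summary statistics that published articles almost
always report: per-dimension Cronbach's alpha, the item count K, and the
correlation r_xy between the manifest composite scores.  Under essential
tau-equivalence,

    AVE_x = alpha_x / (alpha_x * (1 - K_x) + K_x)

(the mean inter-item correlation implied by standardized alpha), and the
latent correlation is recovered by the classical correction for attenuation,
either with both reliabilities ("double correction", r / sqrt(alpha_x *
alpha_y)) or with only the smaller one ("single correction",
r / sqrt(alpha_min)).  For congeneric indicators alpha underestimates
reliability, so the double correction over-corrects (an upper bound on
violation detection) and the single correction under-corrects (a lower
bound); the true criterion always lies between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    DivisionImpossibleError,
    InternalConsistencyError,
    InvalidInputError,
)

__all__ = [
    "DimensionSummary",
    "InstrumentSummary",
    "LoadingSet",
    "PairAssessment",
    "InstrumentAssessment",
    "standardized_alpha",
    "ave_from_loadings",
    "ave_from_alpha",
    "disattenuate",
    "ofl_pair",
    "mfl_pair",
    "assess_pair",
    "assess_instrument",
    "TIE_RTOL",
]

# Relative half-width of the band within which an AVE and a squared
# (corrected) correlation are considered tied.  Ties resolve as "met": a
# violation must exceed numerical noise.  At the exact population threshold
# (e.g. AVE = phi^2 = 0.49 for equal 0.70 loadings at phi = 0.70) different
# float evaluation orders land one ulp apart; without the band the analytic
# decision curves of oFL and mFL-double could disagree there.
TIE_RTOL = 1e-12

Mode = Literal["double", "single"]


def _check_corr_matrix(matrix, *, name: str = "matrix", sym_tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"{name} must be square, got shape {m.shape}")
    if m.shape[0] < 2:
        raise InvalidInputError(f"{name} must be at least 2x2, got {m.shape[0]}")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    if np.max(np.abs(m - m.T)) > sym_tol:
        raise InvalidInputError(f"{name} is not symmetric (tolerance {sym_tol})")
    if np.max(np.abs(np.diag(m) - 1.0)) > sym_tol:
        raise InvalidInputError(f"{name} must have a unit diagonal")
    if np.max(np.abs(m)) > 1.0 + sym_tol:
        raise InvalidInputError(f"{name} has entries outside [-1, 1]")
    return m


@dataclass(frozen=True)
class DimensionSummary:
    """Reliability summary of one instrument dimension.

    Attributes
    ----------
    name : str
        Dimension label.
    alpha : float
        Cronbach's alpha, in (0, 1].
    n_items : int
        Number of indicators K; alpha is undefined for a single item.
    """

    name: str
    alpha: float
    n_items: int

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidInputError(
                f"dimension {self.name!r}: alpha must be in (0, 1], got {self.alpha}"
            )
        if int(self.n_items) != self.n_items or self.n_items < 2:
            raise InvalidInputError(
                f"dimension {self.name!r}: n_items must be an integer >= 2, got {self.n_items}"
            )


@dataclass(frozen=True)
class LoadingSet:
    """Standardized factor loadings of one latent variable's indicators."""

    loadings: np.ndarray

    def __post_init__(self):
        lam = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        if lam.ndim != 1 or lam.size < 2:
            raise InvalidInputError("a loading set needs at least 2 loadings")
        if not np.all(np.isfinite(lam)):
            raise InvalidInputError("loadings must be finite")
        if np.any(lam <= -1.0) or np.any(lam > 1.0):
            raise InvalidInputError("standardized loadings must lie in (-1, 1]")
        object.__setattr__(self, "loadings", lam)

    def __len__(self) -> int:
        return self.loadings.size


@dataclass(frozen=True)
class InstrumentSummary:
    """Dimensions of one instrument plus the composite-score correlations.

    ``composite_corr`` holds the manifest correlations r_xy between the
    unweighted mean (equivalently sum) scores of the dimensions, in the
    order of ``dimensions``.
    """

    dimensions: tuple[DimensionSummary, ...]
    composite_corr: np.ndarray

    def __post_init__(self):
        dims = tuple(self.dimensions)
        if len(dims) < 2:
            raise InvalidInputError("an instrument needs at least 2 dimensions")
        m = _check_corr_matrix(self.composite_corr, name="composite_corr")
        if m.shape[0] != len(dims):
            raise InvalidInputError(
                f"composite_corr is {m.shape[0]}x{m.shape[0]} but there are "
                f"{len(dims)} dimensions"
            )
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "composite_corr", m)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)


@dataclass(frozen=True)
class PairAssessment:
    """All quantities and decisions for one dimension pair.

    ``verdict`` summarises the two corrections: ``distinct_certain`` when
    even the over-correcting double correction finds no violation,
    ``violation_certain`` when even the under-correcting single correction
    flags one, and ``uncertain`` when the two disagree.
    """

    pair: tuple[str, str]
    ave_x: float
    ave_y: float
    r_manifest: float
    r_hat_double: float
    r_hat_single: float
    double_met: bool
    single_met: bool
    verdict: str
    overcorrected_flag: bool


@dataclass(frozen=True)
class InstrumentAssessment:
    """Instrument-level roll-up of all pairwise assessments."""

    pairs: tuple[PairAssessment, ...]
    mfl_met: bool
    frac_not_distinct: float
    frac_violation_certain: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def standardized_alpha(inter_item_corr) -> float:
    """Standardized Cronbach's alpha from an inter-item correlation matrix.

    alpha = K * rbar / (1 + (K - 1) * rbar), with rbar the mean off-diagonal
    correlation.

    Raises
    ------
    InvalidInputError
        Non-square input or fewer than 2 items.
    DegenerateInputError
        rbar <= -1/(K-1), where the denominator is nonpositive and alpha
        undefined.
    """
    m = _check_corr_matrix(inter_item_corr, name="inter_item_corr")
    k = m.shape[0]
    rbar = (m.sum() - np.trace(m)) / (k * (k - 1))
    denom = 1.0 + (k - 1) * rbar
    if denom <= 0.0:
        raise DegenerateInputError(
            f"mean inter-item correlation {rbar:.6g} <= -1/(K-1); alpha undefined"
        )
    return float(k * rbar / denom)


def ave_from_loadings(loadings) -> float:
    """Average variance extracted: mean squared standardized loading."""
    if isinstance(loadings, LoadingSet):
        lam = loadings.loadings
    else:
        lam = np.atleast_1d(np.asarray(loadings, dtype=float))
        if lam.size == 0:
            raise InvalidInputError("empty loading vector")
    return float(np.mean(np.square(lam)))


def ave_from_alpha(alpha: float, n_items: int) -> float:
    """AVE implied by standardized alpha under essential tau-equivalence.

    Inverts the alpha formula: returns alpha / (alpha * (1 - K) + K), the
    mean inter-item correlation (= squared common loading = AVE).
    """
    if not (0.0 < alpha <= 1.0):
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    k = int(n_items)
    if k != n_items or k < 2:
        raise InvalidInputError(f"n_items must be an integer >= 2, got {n_items}")
    return float(alpha / (alpha * (1 - k) + k))


def disattenuate(r_manifest: float, alpha_x: float, alpha_y: float, mode: Mode = "double") -> float:
    """Correct a manifest correlation for attenuation by unreliability.

    mode="double" divides by sqrt(alpha_x * alpha_y); mode="single" divides
    by sqrt(min(alpha_x, alpha_y)) only.  The result may exceed 1 in
    magnitude and is returned unclamped.
    """
    if not np.isfinite(r_manifest) or abs(r_manifest) > 1.0:
        raise InvalidInputError(f"|r_manifest| must be <= 1, got {r_manifest}")
    for label, a in (("alpha_x", alpha_x), ("alpha_y", alpha_y)):
        if a == 0.0:
            raise DivisionImpossibleError(f"{label} is zero; correction undefined")
        if not (0.0 < a <= 1.0):
            raise InvalidInputError(f"{label} must be in (0, 1], got {a}")
    if mode == "double":
        denom = np.sqrt(alpha_x * alpha_y)
    elif mode == "single":
        denom = np.sqrt(min(alpha_x, alpha_y))
    else:
        raise InvalidInputError(f"mode must be 'double' or 'single', got {mode!r}")
    return float(r_manifest / denom)


def _ave_exceeds(ave: float, shared_variance: float) -> bool:
    """AVE-versus-shared-variance comparison with the tie band (ties -> met)."""
    return ave >= shared_variance - TIE_RTOL * max(1.0, abs(shared_variance))


def ofl_pair(ave_x: float, ave_y: float, phi: float) -> bool:
    """Original Fornell-Larcker decision: both AVEs must exceed phi**2."""
    for label, a in (("ave_x", ave_x), ("ave_y", ave_y)):
        if not (0.0 < a <= 1.0):
            raise InvalidInputError(f"{label} must be in (0, 1], got {a}")
    if not np.isfinite(phi) or abs(phi) > 1.0:
        raise InvalidInputError(f"|phi| must be <= 1, got {phi}")
    shared = phi * phi
    return _ave_exceeds(ave_x, shared) and _ave_exceeds(ave_y, shared)


def mfl_pair(
    dim_x: DimensionSummary,
    dim_y: DimensionSummary,
    r_manifest: float,
    mode: Mode = "double",
) -> bool:
    """Manifest Fornell-Larcker decision for one dimension pair.

    Compares each alpha-implied AVE against the squared disattenuated
    composite correlation (r**2 / (alpha_x * alpha_y) for double correction,
    r**2 / alpha_min for single).
    """
    ave_x = ave_from_alpha(dim_x.alpha, dim_x.n_items)
    ave_y = ave_from_alpha(dim_y.alpha, dim_y.n_items)
    r_hat = disattenuate(r_manifest, dim_x.alpha, dim_y.alpha, mode=mode)
    shared = r_hat * r_hat
    return _ave_exceeds(ave_x, shared) and _ave_exceeds(ave_y, shared)


def assess_pair(
    dim_x: DimensionSummary, dim_y: DimensionSummary, r_manifest: float
) -> PairAssessment:
    """Full mFL assessment of one dimension pair under both corrections.

    The double correction over-corrects (upper bound on violations) and the
    single correction under-corrects (lower bound), so only three verdicts
    are reachable; the fourth combination (double met, single violated)
    raises :class:`InternalConsistencyError`.
    """
    ave_x = ave_from_alpha(dim_x.alpha, dim_x.n_items)
    ave_y = ave_from_alpha(dim_y.alpha, dim_y.n_items)
    r_hat_double = disattenuate(r_manifest, dim_x.alpha, dim_y.alpha, mode="double")
    r_hat_single = disattenuate(r_manifest, dim_x.alpha, dim_y.alpha, mode="single")
    double_met = _ave_exceeds(ave_x, r_hat_double**2) and _ave_exceeds(ave_y, r_hat_double**2)
    single_met = _ave_exceeds(ave_x, r_hat_single**2) and _ave_exceeds(ave_y, r_hat_single**2)

    if double_met and not single_met:
        raise InternalConsistencyError(
            f"pair ({dim_x.name}, {dim_y.name}): double correction met while "
            "single correction violated — impossible since r^2/alpha_min <= "
            "r^2/(alpha_x*alpha_y)"
        )
    if double_met:
        verdict = "distinct_certain"
    elif single_met:
        verdict = "uncertain"
    else:
        verdict = "violation_certain"

    return PairAssessment(
        pair=(dim_x.name, dim_y.name),
        ave_x=ave_x,
        ave_y=ave_y,
        r_manifest=float(r_manifest),
        r_hat_double=r_hat_double,
        r_hat_single=r_hat_single,
        double_met=double_met,
        single_met=single_met,
        verdict=verdict,
        overcorrected_flag=bool(abs(r_hat_double) > 1.0 or abs(r_hat_single) > 1.0),
    )


def assess_instrument(instr: InstrumentSummary) -> InstrumentAssessment:
    """Assess every non-redundant dimension pair of an instrument.

    Returns one :class:`PairAssessment` per unordered pair (D*(D-1)/2 of
    them) plus the instrument-level summary: mFL is met only when *every*
    pair is ``distinct_certain``; the two violation fractions count pairs
    with verdict != distinct_certain and verdict == violation_certain.
    """
    dims = instr.dimensions
    r = instr.composite_corr
    pairs = []
    for i in range(len(dims)):
        for j in range(i + 1, len(dims)):
            pairs.append(assess_pair(dims[i], dims[j], r[i, j]))
    n = len(pairs)
    n_not_distinct = sum(1 for p in pairs if p.verdict != "distinct_certain")
    n_violation = sum(1 for p in pairs if p.verdict == "violation_certain")
    return InstrumentAssessment(
        pairs=tuple(pairs),
        mfl_met=(n_not_distinct == 0),
        frac_not_distinct=n_not_distinct / n,
        frac_violation_certain=n_violation / n,
    )
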
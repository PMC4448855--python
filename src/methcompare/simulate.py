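"""Synthetic data generators.

Everything the analysis layer consumes can be generated here with known
ground truth: the canonical 12-region worked example, equal-tendency
permutation nulls, a differential-methylation simulation with per-row
labels, and a deamination-coupled generator in which CpG observation
density depends on methylation class — the mechanism (loss of CpGs in
constitutively methylated, weakly selected regions) that produces the
Yule-Simpson bias in real vertebrate methylomes.

Generator defaults define the desk-scale study conditions used by the
test suite; see ``docs/methods.md`` for the rationale behind each value
and for what these simulations do and do not capture about real
bisulfite data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .matrix import AggregationMatrix, JunctionMatrixPair
from .randomization import shuffle_pair

__all__ = [
    "fig1_pair", "simpson_reversal_pair", "equal_tendency_null",
    "differential_simulation", "DeaminationParams", "DeaminationTruth",
    "deamination_pair", "graded_tendency_matrix",
]


def fig1_pair() -> JunctionMatrixPair:
    """The deterministic 12-region worked example.

    Twelve regions span a boundary; in eight all CpGs are fully
    methylated, in the remaining four fully unmethylated.  On the left
    side each methylated region retains a single CpG (two regions per
    column over four columns) while unmethylated regions keep all four;
    on the right side every region keeps all four.  Both sides have
    identical regional tendencies (R = 2/3), yet the column-average
    statistic steps from C = 1/3 on the left to C = 2/3 on the right —
    the canonical Yule-Simpson artifact.  The left matrix satisfies
    C = M = 1/3, R = 2/3 exactly.
    """
    n, m = 12, 4
    left = np.full((n, m), np.nan)
    for i in range(8):           # methylated regions: one CpG each
        left[i, i // 2] = 1.0
    left[8:, :] = 0.0            # unmethylated regions: fully observed
    right = np.zeros((n, m))
    right[:8, :] = 1.0
    labels = [f"j{i + 1}" for i in range(n)]
    return JunctionMatrixPair(
        AggregationMatrix(left, row_labels=labels),
        AggregationMatrix(right, row_labels=labels),
        row_labels=labels)


def simpson_reversal_pair() -> tuple:
    """Two matrices exhibiting Simpson's paradox for (R, C).

    Returns ``(W1, W2)`` with ``R_1 > R_2`` but ``C_1 < C_2``: W1 is the
    sparse methylated-region matrix of the worked example
    (R = 2/3, C = 1/3) and W2 a fully observed matrix of constant 1/2
    (R = C = 1/2).  A sign flip between the row-average and
    column-average comparison is an instance of Simpson's paradox.
    """
    w1 = fig1_pair().left
    w2 = AggregationMatrix(np.full((12, 4), 0.5))
    return w1, w2


def equal_tendency_null(pair: JunctionMatrixPair, seed=None,
                        shuffle_mask: bool = False) -> JunctionMatrixPair:
    """Simulate equal methylation tendency across the boundary.

    The default delegates to
    :func:`methcompare.randomization.shuffle_pair`: observed values are
    permuted within each coupled row while the missingness structure is
    frozen, so any residual cross-boundary step is pure Yule-Simpson
    artifact.  With ``shuffle_mask=True`` the whole row — values *and*
    missing positions together — is permuted, additionally equalizing
    the selective (CpG-density) structure across the boundary.
    """
    if not shuffle_mask:
        return shuffle_pair(pair, seed=seed)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values = np.hstack([pair.left.values, pair.right.values])
    mask = np.hstack([pair.left.mask, pair.right.mask])
    for i in range(values.shape[0]):
        perm = rng.permutation(values.shape[1])
        values[i] = values[i, perm]
        mask[i] = mask[i, perm]
    ml = pair.left.m
    return JunctionMatrixPair(
        AggregationMatrix(values[:, :ml], mask[:, :ml],
                          list(pair.left.row_labels)),
        AggregationMatrix(values[:, ml:], mask[:, ml:],
                          list(pair.right.row_labels)),
        row_labels=list(pair.row_labels))


def differential_simulation(pair: JunctionMatrixPair,
                            diff_fraction: float = 0.05,
                            threshold: float = 0.5,
                            boundary_column_substitution: bool = False,
                            seed=None) -> tuple:
    """Binarize a pair by regional tendency and plant known differences.

    Each coupled row is set fully methylated (all observed cells 1) when
    its joined mean is at least ``threshold``, else fully unmethylated.
    ``round(n_methylated * diff_fraction)`` methylated rows (at least one
    when the fraction is positive) are then drawn uniformly and their
    *left*-side observed cells set to 0 — the planted differential
    class.  With ``boundary_column_substitution`` each side's three
    boundary-adjacent columns are replaced wholesale (values and mask)
    by the adjacent three, compensating for the scarcity of CpGs
    immediately at real junctions; otherwise the mask is preserved
    exactly.

    Returns ``(pair, labels)`` where ``labels`` is an array over rows
    with values ``"unmethylated"``, ``"methylated"`` or
    ``"differential"``.
    """
    if not 0 <= diff_fraction <= 1:
        raise ValidationError("diff_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = np.hstack([pair.left.values, pair.right.values])
    mask = np.hstack([pair.left.mask, pair.right.mask])
    cnt = mask.sum(axis=1)
    if (cnt == 0).any():
        raise ValidationError(
            "every coupled row needs >= 1 observed value")
    means = np.where(mask, values, 0.0).sum(axis=1) / cnt
    meth = means >= threshold
    n_meth = int(meth.sum())
    if n_meth == 0:
        raise ValidationError("no methylated rows to differentiate")

    values = np.where(mask, np.where(meth[:, None], 1.0, 0.0), np.nan)

    n_diff = int(round(n_meth * diff_fraction))
    if diff_fraction > 0:
        n_diff = max(n_diff, 1)
    diff_rows = rng.choice(np.flatnonzero(meth), size=n_diff,
                           replace=False)
    ml = pair.left.m
    values[np.ix_(diff_rows, np.arange(ml))] = np.where(
        mask[np.ix_(diff_rows, np.arange(ml))], 0.0, np.nan)

    labels = np.where(meth, "methylated", "unmethylated").astype(object)
    labels[diff_rows] = "differential"

    left_v, right_v = values[:, :ml].copy(), values[:, ml:].copy()
    left_m, right_m = mask[:, :ml].copy(), mask[:, ml:].copy()
    if boundary_column_substitution:
        if ml < 6 or pair.right.m < 6:
            raise ValidationError(
                "boundary column substitution needs >= 6 columns per side")
        for v, mk in ((left_v, left_m), (right_v, right_m)):
            v[:, 0:3] = v[:, 3:6]
            mk[:, 0:3] = mk[:, 3:6]

    out = JunctionMatrixPair(
        AggregationMatrix(left_v, left_m, list(pair.left.row_labels)),
        AggregationMatrix(right_v, right_m, list(pair.right.row_labels)),
        row_labels=list(pair.row_labels))
    return out, labels


# ---------------------------------------------------------------------------
# Deamination-coupled generator
# ---------------------------------------------------------------------------

@dataclass
class DeaminationParams:
    """Study conditions for the deamination-coupled generator.

    Each region is methylated with probability ``p_methylated``; its
    true tendency is 1 (methylated) or 0, with the right side shifted by
    ``true_step`` and clipped to [0, 1].  Every cell is observed (the
    position retains a CpG) with a probability depending on the region's
    class and side — lowering the density for methylated regions on one
    side models deamination having eroded CpGs there.  Observed values
    are the true tendency plus truncated-Gaussian jitter (bisulfite
    rates at modest coverage are noisy fractions).

    Defaults encode the contrast used throughout the tests: 400 regions,
    10 columns per side, 60 % methylated, methylated-left density 0.1
    against 0.8 everywhere else, jitter SD 0.05, no true step.
    """

    n: int = 400
    m: int = 10
    p_methylated: float = 0.6
    cg_density_meth_left: float = 0.1
    cg_density_unmeth_left: float = 0.8
    cg_density_meth_right: float = 0.8
    cg_density_unmeth_right: float = 0.8
    noise_sd: float = 0.05
    true_step: float = 0.0
    seed: object = None

    def validate(self):
        if self.n < 1 or self.m < 1:
            raise ValidationError("n and m must be >= 1")
        for name in ("p_methylated", "cg_density_meth_left",
                     "cg_density_unmeth_left", "cg_density_meth_right",
                     "cg_density_unmeth_right"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class DeaminationTruth:
    """Ground truth accompanying a generated pair."""

    methylated: np.ndarray       # bool per region
    tendency_left: np.ndarray    # true tendency per region, left side
    tendency_right: np.ndarray

    @property
    def mean_tendency_left(self) -> float:
        return float(self.tendency_left.mean())

    @property
    def mean_tendency_right(self) -> float:
        return float(self.tendency_right.mean())


def _jittered(tendency, mask, noise_sd, rng):
    """Tendency + Gaussian jitter truncated to [0, 1], at observed cells."""
    n, m = mask.shape
    base = np.repeat(tendency[:, None], m, axis=1)
    if noise_sd == 0:
        return np.where(mask, base, np.nan)
    a = (0.0 - base) / noise_sd
    b = (1.0 - base) / noise_sd
    noise = stats.truncnorm.rvs(a, b, loc=base, scale=noise_sd,
                                size=(n, m), random_state=rng)
    return np.where(mask, noise, np.nan)


def deamination_pair(params: DeaminationParams) -> tuple:
    """Generate a coupled pair under deamination-coupled missingness.

    Returns ``(pair, truth)``.  Raises
    :class:`~methcompare.errors.ValidationError` when a side ends up
    with no observed cell at all (degenerate densities).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.n, params.m
    meth = rng.random(n) < params.p_methylated
    t_left = meth.astype(float)
    t_right = np.clip(t_left + params.true_step, 0.0, 1.0)

    dens_left = np.where(meth, params.cg_density_meth_left,
                         params.cg_density_unmeth_left)
    dens_right = np.where(meth, params.cg_density_meth_right,
                          params.cg_density_unmeth_right)
    mask_left = rng.random((n, m)) < dens_left[:, None]
    mask_right = rng.random((n, m)) < dens_right[:, None]
    if not mask_left.any() or not mask_right.any():
        raise ValidationError(
            "degenerate parameters: a side has no observed cells")

    vals_left = _jittered(t_left, mask_left, params.noise_sd, rng)
    vals_right = _jittered(t_right, mask_right, params.noise_sd, rng)
    labels = [f"j{i}" for i in range(n)]
    pair = JunctionMatrixPair(
        AggregationMatrix(vals_left, mask_left, labels),
        AggregationMatrix(vals_right, mask_right, labels),
        row_labels=labels)
    return pair, DeaminationTruth(methylated=meth, tendency_left=t_left,
                                  tendency_right=t_right)


def graded_tendency_matrix(n: int = 800, m: int = 10,
                           density: float = 0.5, noise_sd: float = 0.05,
                           low: float = 0.1, high: float = 0.9,
                           seed=None) -> tuple:
    """A single matrix with continuous per-region tendencies.

    Row tendencies are uniform on ``[low, high]``, cells observed i.i.d.
    with probability ``density``, observed values jittered around the
    row tendency.  Useful for calibration checks (cross-validation TLS
    slope) where binary tendencies would make the fit separable.
    Returns ``(matrix, tendencies)``.
    """
    rng = np.random.default_rng(seed)
    tendencies = rng.uniform(low, high, size=n)
    mask = rng.random((n, m)) < density
    if not mask.any():
        raise ValidationError("degenerate parameters: no observed cells")
    values = _jittered(tendencies, mask, noise_sd, rng)
    return AggregationMatrix(values, mask), tendencies
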
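"""Mutational-equilibrium dinucleotide content from the 16x16 rate matrix.

The 96 normalized dinucleotide mutation rates define a continuous-time
Markov chain on the 16 dinucleotides (off-diagonal entries are the
single-base-change rates; each row sums to zero).  Its stationary
distribution is the dinucleotide content the genome would drift to if
mutation alone acted indefinitely.  Comparing that prediction with the
observed intergenic dinucleotide content exposes artifact classes: bleed
errors over-call mutations resolving to AA/TT, so their equilibrium AA/TT
frequencies overshoot as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .io_formats import AnnotationSet, GenomeAssembly
from .mutation_spectrum import (
    CLASS_KEYS,
    DINUCS,
    DiSpectrum96,
    class_parts,
    dinucleotide_counts,
)


@dataclass
class MutationMatrix16:
    """Rate matrix Q over the 16 dinucleotides (rows sum to zero)."""

    rates: pd.DataFrame                # 16x16, index/columns = DINUCS
    source_spectrum: DiSpectrum96 | None = None

    @property
    def q(self) -> np.ndarray:
        return self.rates.to_numpy()


@dataclass
class EquilibriumResult:
    predicted_freq: pd.Series
    observed_freq: pd.Series
    slope: float
    intercept: float
    r: float
    outlier_p: dict[str, float]        # per designated state, uncorrected
    outlier_p_joint: float             # max-|residual| test, Sidak-corrected
    outlier_residuals: dict[str, float]


def build_matrix(spectrum: DiSpectrum96) -> MutationMatrix16:
    """Assemble Q from the 96 normalized class rates.

    The rate from dinucleotide X to Y is the normalized rate of the unique
    single-base class converting X to Y; dinucleotides differing at both
    positions have structural-zero rates.  NaN rates (absent context) are
    treated as zero.
    """
    rate = spectrum.normalized_rate.fillna(0.0)
    if float(rate.sum()) == 0.0:
        raise ValueError("all class rates are zero; cannot build a rate matrix")
    q = pd.DataFrame(0.0, index=DINUCS, columns=DINUCS)
    for key in CLASS_KEYS:
        src, tgt = key.split(">")
        q.loc[src, tgt] += float(rate[key])
    np.fill_diagonal(q.values, 0.0)
    q.values[np.diag_indices(16)] = -q.sum(axis=1).to_numpy()
    return MutationMatrix16(rates=q, source_spectrum=spectrum)


def _check_irreducible(q: np.ndarray) -> None:
    adjacency = (q > 0).astype(int)
    n, labels = connected_components(adjacency, directed=True, connection="strong")
    if n > 1:
        components = {}
        for state, lab in zip(DINUCS, labels):
            components.setdefault(int(lab), []).append(state)
        raise ValueError(
            f"dinucleotide chain is reducible; strongly connected components: "
            f"{sorted(components.values())}")


def stationary_distribution(matrix: MutationMatrix16) -> pd.Series:
    """The unique probability vector pi with pi . Q = 0.

    Solved as a constrained linear system and cross-checked internally by
    power iteration on the embedded discrete chain.
    """
    q = matrix.q
    _check_irreducible(q)
    a = np.vstack([q.T, np.ones(16)])
    b = np.zeros(17)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    # internal cross-check: power iteration on P = I + Q*dt
    dt = 0.5 / np.abs(np.diag(q)).max()
    p = np.eye(16) + q * dt
    v = np.full(16, 1 / 16)
    for _ in range(200_000):
        nxt = v @ p
        if np.abs(nxt - v).max() < 1e-14:
            v = nxt
            break
        v = nxt
    v = v / v.sum()
    if np.abs(v - pi).max() > 1e-6:  # pragma: no cover
        raise RuntimeError("stationary solve and power iteration disagree")
    return pd.Series(pi, index=DINUCS, name="predicted_freq")


def _studentized_outlier(x: np.ndarray, y: np.ndarray, x0: float, y0: float
                         ) -> tuple[float, float]:
    """Externally studentized prediction residual of (x0, y0) against an OLS
    fit of y on x (the point itself excluded); two-sided t p-value."""
    from scipy import stats
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = n - 2
    s2 = float(resid @ resid) / dof
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    se = np.sqrt(s2 * (1 + 1 / n + (x0 - xbar) ** 2 / sxx))
    t = (y0 - (slope * x0 + intercept)) / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(t), float(p)


def observed_dinucleotide_freq(genome: GenomeAssembly,
                               annotation: AnnotationSet) -> pd.Series:
    """Observed dinucleotide frequencies over intergenic space."""
    intervals = [(iv.chrom, iv.start, iv.end)
                 for iv in annotation.of_type("intergenic")]
    if not intervals:
        raise ValueError("annotation has no intergenic intervals")
    counts = dinucleotide_counts(genome, intervals)
    return counts / counts.sum()


def equilibrium_vs_observed(
    matrix: MutationMatrix16,
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    outlier_states: tuple[str, ...] = ("AA", "TT"),
) -> EquilibriumResult:
    """Predicted equilibrium vs observed intergenic dinucleotide content.

    Fits predicted on observed by least squares over the 16 states, then
    tests whether the designated states are outliers: the fit is recomputed
    excluding them, each one's externally studentized prediction residual is
    converted to a two-sided t p-value, and the joint p-value takes the
    maximum absolute residual with Sidak correction for the number of
    designated states.
    """
    predicted = stationary_distribution(matrix)
    observed = observed_dinucleotide_freq(genome, annotation)
    if (observed <= 0).any():
        absent = list(observed.index[observed <= 0])
        raise ValueError(f"degenerate observed frequencies; absent states: {absent}")
    x_all = observed.to_numpy()
    y_all = predicted.to_numpy()
    slope, intercept = np.polyfit(x_all, y_all, 1)
    r = float(np.corrcoef(x_all, y_all)[0, 1])
    keep = ~observed.index.isin(outlier_states)
    x_fit, y_fit = x_all[keep], y_all[keep]
    outlier_p: dict[str, float] = {}
    outlier_t: dict[str, float] = {}
    for state in outlier_states:
        i = DINUCS.index(state)
        t, p = _studentized_outlier(x_fit, y_fit, x_all[i], y_all[i])
        outlier_t[state] = t
        outlier_p[state] = p
    p_min = min(outlier_p.values()) if outlier_p else 1.0
    joint = 1.0 - (1.0 - p_min) ** len(outlier_p) if outlier_p else 1.0
    return EquilibriumResult(
        predicted_freq=predicted, observed_freq=observed,
        slope=float(slope), intercept=float(intercept), r=r,
        outlier_p=outlier_p, outlier_p_joint=float(joint),
        outlier_residuals=outlier_t)
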
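"""Low-rank thin-plate regression spline basis for 1D covariates.

The full thin-plate spline for one covariate uses the radial basis
eta(r) = r^3 / 12 on every data point plus an unpenalised linear null
space.  Following the usual low-rank construction, the radial part is
truncated to the leading k eigenvectors of the kernel matrix and the
null-space orthogonality constraint is absorbed, giving k - 2 penalised
columns with a positive semi-definite wiggliness penalty plus one linear
column.  Columns are centred over the training covariate so every smooth
sums to zero on the training data.

The basis also exposes a "mixed" reparameterisation (penalty = identity)
used to fit smooths as random-effect blocks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

#: cap on the number of radial knots (computation is O(m^3) in knots)
MAX_KNOTS = 200


def _eta(r: np.ndarray) -> np.ndarray:
    return r ** 3 / 12.0


class SmoothBasis:
    """Thin-plate regression spline basis of dimension ``k`` for one covariate.

    Attributes
    ----------
    design : ndarray (n, k-1)
        Centred training design: column 0 is the (centred, rescaled) linear
        term, columns 1..k-2 are the penalised radial columns.
    penalty : ndarray (k-1, k-1)
        Wiggliness penalty on ``design``'s coefficients: zero for the
        linear column, positive semi-definite block for the rest.
    """

    def __init__(self, x: np.ndarray, k: int = 10, max_knots: int = MAX_KNOTS):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("x must be 1-dimensional")
        xu = np.unique(x)
        if xu.size < 3:
            raise ValueError("need at least 3 distinct covariate values")
        if xu.size < k:
            warnings.warn(f"only {xu.size} distinct values; reducing basis "
                          f"dimension from {k} to {xu.size}")
            k = xu.size
        self.k = int(k)

        # rescale to [0, 1] for conditioning
        self._x0 = float(xu.min())
        self._scale = float(xu.max() - xu.min()) or 1.0
        xs = (x - self._x0) / self._scale
        knots = (xu - self._x0) / self._scale
        if knots.size > max_knots:
            qs = np.linspace(0, 1, max_knots)
            knots = np.unique(np.quantile(knots, qs))
        self._knots = knots

        m = knots.size
        E = _eta(np.abs(knots[:, None] - knots[None, :]))
        T = np.column_stack([np.ones(m), knots])
        eigval, eigvec = linalg.eigh(E)
        keep = np.argsort(np.abs(eigval))[::-1][: self.k]
        Dk = eigval[keep]
        Uk = eigvec[:, keep]
        # absorb the null-space constraint T' U_k z = 0
        Zc = linalg.null_space(T.T @ Uk)  # (k, k-2)
        self._A_raw = Uk @ Zc  # knots -> raw penalised columns
        S = Zc.T @ (Dk[:, None] * Zc)
        S = (S + S.T) / 2.0
        self._S = S

        # mixed reparameterisation: columns with identity penalty
        lam, V = linalg.eigh(S)
        lam = np.maximum(lam, lam.max() * 1e-10)
        self._A_mixed = self._A_raw @ (V / np.sqrt(lam))

        self._x_mean = float(np.mean(xs))
        raw = _eta(np.abs(xs[:, None] - knots[None, :]))
        pen_raw = raw @ self._A_raw
        pen_mix = raw @ self._A_mixed
        self._raw_means = pen_raw.mean(axis=0)
        self._mix_means = pen_mix.mean(axis=0)
        self._xs_train = xs

        self.design = np.column_stack([xs - self._x_mean,
                                       pen_raw - self._raw_means])
        self.penalty = linalg.block_diag(np.zeros((1, 1)), S)

    # -- evaluation --------------------------------------------------------
    def _rescale(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self._x0) / self._scale

    def linear_column(self, x) -> np.ndarray:
        return self._rescale(x) - self._x_mean

    def mixed_columns(self, x) -> np.ndarray:
        """Identity-penalty radial columns at new covariate values, centred
        with the training column means."""
        xs = self._rescale(x)
        raw = _eta(np.abs(xs[:, None] - self._knots[None, :]))
        return raw @ self._A_mixed - self._mix_means

    @property
    def n_mixed(self) -> int:
        return self._A_mixed.shape[1]

    def to_dict(self) -> dict:
        """JSON-serialisable description sufficient for re-evaluation."""
        return {
            "k": self.k,
            "x0": self._x0,
            "scale": self._scale,
            "x_mean": self._x_mean,
            "knots": self._knots.tolist(),
            "A_mixed": self._A_mixed.tolist(),
            "mix_means": self._mix_means.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SmoothBasis":
        """Rebuild a basis for prediction from :meth:`to_dict` output."""
        obj = cls.__new__(cls)
        obj.k = int(doc["k"])
        obj._x0 = float(doc["x0"])
        obj._scale = float(doc["scale"])
        obj._x_mean = float(doc["x_mean"])
        obj._knots = np.asarray(doc["knots"], dtype=float)
        obj._A_mixed = np.asarray(doc["A_mixed"], dtype=float)
        obj._mix_means = np.asarray(doc["mix_means"], dtype=float)
        return obj


def build_smooth_basis(x, k: int = 10):
    """Build the TPRS basis; returns (design columns, penalty matrix).

    The full :class:`SmoothBasis` object is available as the third element
    for callers needing prediction at new covariate values.
    """
    basis = SmoothBasis(x, k)
    return basis.design, basis.penalty, basis
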
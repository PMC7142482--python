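"""Relative metabolite quantification by constrained library fitting.

Each sample spectrum s is modeled as a non-negative combination of
unit-total-intensity standard spectra (the rows of a
:class:`SpectralLibrary`):

    minimize  || s - M^T c ||_2^2   subject to  c >= 0

A partial-least-squares regression of the spectrum on the library provides
the starting point (negative entries clipped to zero).  The constrained
problem is then solved by Levenberg-Marquardt on the squared
parameterization c = u**2, which keeps the iteration unconstrained while
enforcing non-negativity exactly.  Because the forward model is linear the
result must agree with an exact active-set non-negative least-squares solve;
that equivalence is the package's principal correctness contract and is
enforced in the test suite against ``scipy.optimize.nnls``.

Fitted coefficients are relative concentrations on the common standard scale
set by the unit-intensity library; they are comparable across samples but are
not absolute (mM) amounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.cross_decomposition import PLSRegression

from .spectra import Spectrum
from .synthdata import MetaboliteDef, make_reference_spectrum

LIBRARY_ROW_TOL = 1e-9
CONDITION_WARN = 1e8
DEFAULT_MAX_ITER = 500
ZERO_SNAP_REL = 1e-9


class QuantificationError(ValueError):
    pass


@dataclass
class SpectralLibrary:
    """Matrix of unit-total-intensity standard spectra on a shared grid."""

    names: list[str]
    matrix: np.ndarray  # metabolites x grid points
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise QuantificationError("library names must be unique")
        if self.matrix.shape != (len(self.names), self.grid.size):
            raise QuantificationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.names)} names x {self.grid.size} grid points"
            )
        sums = self.matrix.sum(axis=1)
        off = np.abs(sums - 1.0) > LIBRARY_ROW_TOL
        if off.any():
            bad = [self.names[i] for i in np.where(off)[0]]
            raise QuantificationError(
                f"library rows must have unit total intensity; offending: {bad}"
            )
        self._cond: float | None = None

    @property
    def n_metabolites(self) -> int:
        return len(self.names)

    @property
    def condition_number(self) -> float:
        if self._cond is None:
            self._cond = float(np.linalg.cond(self.matrix @ self.matrix.T) ** 0.5)
        return self._cond

    @classmethod
    def from_definitions(
        cls, defs: Sequence[MetaboliteDef], grid: np.ndarray
    ) -> "SpectralLibrary":
        refs = [make_reference_spectrum(m, grid) for m in defs]
        return cls([m.name for m in defs], np.vstack([r.intensity for r in refs]), grid)

    @classmethod
    def from_directory(cls, directory: str | Path, manifest: str = "manifest.csv") -> "SpectralLibrary":
        """Load standards from two-column TSVs listed in a manifest CSV (name, file)."""
        directory = Path(directory)
        man = pd.read_csv(directory / manifest)
        names, rows, grid = [], [], None
        for _, rec in man.iterrows():
            df = pd.read_csv(directory / rec["file"], sep="\t")
            ppm = df.iloc[:, 0].to_numpy(float)
            if grid is None:
                grid = ppm
            elif not np.allclose(grid, ppm):
                raise QuantificationError(f"{rec['file']}: grid differs from the first standard")
            names.append(rec["name"])
            rows.append(df.iloc[:, 1].to_numpy(float))
        if grid is None:
            raise QuantificationError(f"{directory / manifest}: empty manifest")
        return cls(names, np.vstack(rows), grid)

    def write_directory(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        records = []
        for name, row in zip(self.names, self.matrix):
            fname = f"{name.replace('/', '_')}.tsv"
            pd.DataFrame({"ppm": self.grid, "intensity": row}).to_csv(
                directory / fname, sep="\t", index=False, float_format="%.12g"
            )
            records.append({"name": name, "file": fname})
        pd.DataFrame(records).to_csv(directory / "manifest.csv", index=False)

    def design_for(self, s: Spectrum) -> np.ndarray:
        """Library columns matched to the spectrum's (possibly trimmed) grid.

        The spectrum axis must be a subset of the library grid (exact values),
        so water-excluded or trimmed spectra fit against the same standards.
        """
        if s.ppm.size == self.grid.size and np.allclose(s.ppm, self.grid):
            return self.matrix
        idx = np.searchsorted(self.grid, s.ppm)
        idx = np.clip(idx, 0, self.grid.size - 1)
        if not np.allclose(self.grid[idx], s.ppm, rtol=0, atol=1e-9):
            raise QuantificationError(
                "spectrum grid is not a subset of the library grid"
            )
        return self.matrix[:, idx]


@dataclass
class FitDiagnostics:
    """Residual norm, iteration count, convergence flag and the PLS start."""

    residual_norm: float
    iterations: int
    converged: bool
    initial_vector: np.ndarray = field(repr=False, default=None)


def pls_initialize(
    library: SpectralLibrary, s: Spectrum, n_components: int | None = None
) -> np.ndarray:
    """PLS regression of the spectrum on the library rows, clipped to >= 0."""
    M = library.design_for(s)
    y = s.intensity
    if not np.any(y):
        return np.zeros(library.n_metabolites)
    k = library.n_metabolites
    if n_components is None:
        n_components = min(10, k)
    if not 1 <= n_components <= k:
        raise QuantificationError(
            f"n_components must be in [1, {k}], got {n_components}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # residual-deflation warnings on exact fits
        pls.fit(M.T, y)
    coef = np.asarray(pls.coef_).reshape(-1)
    return np.clip(coef, 0.0, None)


def fit_concentrations(
    library: SpectralLibrary,
    s: Spectrum,
    init: np.ndarray | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Non-negative library fit by Levenberg-Marquardt on c = u**2.

    Starting from u = sqrt(init) (the PLS initialization by default, floored
    slightly above zero so no coefficient starts on the stationary boundary),
    LM minimizes ||M^T u**2 - s||.  Coefficients that converge to the
    non-negativity boundary are snapped to exactly zero and the remaining
    support is re-polished with a second short LM run.
    """
    M = library.design_for(s)
    y = s.intensity
    if library.condition_number > CONDITION_WARN:
        warnings.warn(
            f"library condition number {library.condition_number:.3g} > {CONDITION_WARN:.0e}; "
            "coefficients of collinear standards are not identifiable",
            stacklevel=2,
        )
    if init is None:
        init = pls_initialize(library, s)
    init = np.asarray(init, dtype=float)
    if init.shape != (library.n_metabolites,):
        raise QuantificationError("init vector length does not match the library")
    if not np.any(y):
        return np.zeros_like(init), FitDiagnostics(0.0, 0, True, init.copy())

    MT = M.T  # grid x metabolites

    def residual(u: np.ndarray) -> np.ndarray:
        return MT @ (u * u) - y

    def jacobian(u: np.ndarray) -> np.ndarray:
        return MT * (2.0 * u)

    scale = init.max()
    floor = 1e-3 * scale if scale > 0 else 1e-3 * max(np.abs(y).max(), 1e-12)
    u0 = np.sqrt(np.maximum(init, floor))
    res = least_squares(
        residual,
        u0,
        jac=jacobian,
        method="lm",
        ftol=ftol,
        xtol=xtol,
        gtol=1e-14,
        max_nfev=max_iter * library.n_metabolites,
    )
    c = res.x**2
    iterations = int(res.nfev)
    converged = bool(res.status > 0)

    snap = ZERO_SNAP_REL * max(c.max(), 1e-30)
    on_boundary = c < snap
    if on_boundary.any() and not on_boundary.all():
        c = np.where(on_boundary, 0.0, c)
        res = least_squares(
            residual,
            np.sqrt(c),
            jac=jacobian,
            method="lm",
            ftol=ftol,
            xtol=xtol,
            gtol=1e-14,
            max_nfev=max_iter * library.n_metabolites,
        )
        c = res.x**2
        c[c < snap] = 0.0
        iterations += int(res.nfev)
        converged = converged and bool(res.status > 0)
    elif on_boundary.all():
        c = np.zeros_like(c)

    diag = FitDiagnostics(
        residual_norm=float(np.linalg.norm(MT @ c - y)),
        iterations=iterations,
        converged=converged,
        initial_vector=init.copy(),
    )
    return c, diag


def _normalization_signature(s: Spectrum) -> tuple:
    return tuple(
        (h["op"], tuple(sorted((k, str(v)) for k, v in h.items() if k != "op")))
        for h in s.history
        if h["op"].startswith("normalize")
    )


def quantify_cohort(
    library: SpectralLibrary,
    spectra: Sequence[Spectrum],
    n_components: int | None = None,
    diagnostics: list[FitDiagnostics] | None = None,
) -> pd.DataFrame:
    """Fit every spectrum against the library; rows follow the input order.

    All spectra must share one normalization mode (identical normalization
    history); mixing reference-peak- and total-area-normalized spectra would
    put samples on incomparable scales, so it is refused.
    """
    spectra = list(spectra)
    if not spectra:
        return pd.DataFrame(columns=library.names)
    signatures = {_normalization_signature(s) for s in spectra}
    if len(signatures) > 1:
        raise QuantificationError(
            "spectra carry different normalization histories; "
            "renormalize the cohort with a single mode before quantification"
        )
    rows, ids = [], []
    for i, s in enumerate(spectra):
        init = pls_initialize(library, s, n_components)
        c, diag = fit_concentrations(library, s, init)
        if diagnostics is not None:
            diagnostics.append(diag)
        rows.append(c)
        ids.append(s.meta.get("sample_id", f"sample_{i}"))
    return pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="sample_id"), columns=library.names
    )
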
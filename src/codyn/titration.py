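"""Chemical-shift-perturbation titration analysis and global K_D fitting.

A ligand titration followed by 2D amide NMR yields, for each residue, the
changes in amide 1H and 15N chemical shifts at a series of ligand
concentrations.  The two dimensions are combined into a single weighted CSP

    CSP = sqrt((ddH * W_H)^2 + (ddN * W_N)^2),    W_H = 1, W_N = 0.154,

the 15N weight compensating for the wider 15N shift dispersion.  Residues
whose CSP at a chosen ligand point exceeds a cutoff (strictly, by
convention 0.05 ppm at 2 mM) are treated as binders and fitted
simultaneously with a one-site model that accounts for ligand depletion
(protein and ligand concentrations are comparable at mM K_D):

    CSP(L) = d0 * [P + L + K_D - sqrt((P + L + K_D)^2 - 4 P L)] / (2 P)

with one shared K_D and one saturation amplitude d0 per residue.  The fit
runs on raw (unnormalised) CSPs; normalisation by the fitted d0 is
display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .errors import FitError

__all__ = [
    "CSPWeights",
    "DEFAULT_WEIGHTS",
    "TitrationSet",
    "BindingFitResult",
    "combined_csp",
    "isotherm_csp",
    "select_binders",
    "fit_global",
    "normalize_for_plot",
    "read_titration_table",
    "write_titration_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CSPWeights:
    """Dimensionless weights for the 1H and 15N shift dimensions."""

    w_h: float = 1.0
    w_n: float = 0.154

    def __post_init__(self):
        if self.w_h <= 0 or self.w_n <= 0:
            raise ValueError("CSP weights must be positive")


DEFAULT_WEIGHTS = CSPWeights()


@dataclass
class TitrationSet:
    """Per-residue titration series on a common ligand grid.

    ``ddh``/``ddn`` are (n_residues, n_ligand_points) arrays of amide 1H
    and 15N shift changes in ppm relative to the apo spectrum; ``ligand``
    is the shared ligand-concentration grid in mM and ``protein`` the
    (fixed) protein concentration in mM.
    """

    protein: float  # mM
    ligand: np.ndarray  # (L,), mM
    residues: np.ndarray  # (R,) residue ids
    ddh: np.ndarray  # (R, L) ppm
    ddn: np.ndarray  # (R, L) ppm

    def __post_init__(self):
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.residues = np.asarray(self.residues)
        self.ddh = np.asarray(self.ddh, dtype=float)
        self.ddn = np.asarray(self.ddn, dtype=float)
        if self.protein <= 0:
            raise ValueError("protein concentration must be positive")
        if np.any(self.ligand < 0):
            raise ValueError("ligand concentrations must be non-negative")
        shape = (self.residues.size, self.ligand.size)
        if self.ddh.shape != shape or self.ddn.shape != shape:
            raise ValueError(
                f"shift arrays must have shape {shape} (residues x ligand points)"
            )

    def csp(self, weights: CSPWeights = DEFAULT_WEIGHTS) -> np.ndarray:
        """Combined CSP matrix, shape (n_residues, n_ligand_points)."""
        return combined_csp(self.ddh, self.ddn, weights)


@dataclass
class BindingFitResult:
    """Global one-site fit: shared K_D plus per-residue saturation CSPs."""

    kd: float  # mM
    kd_stderr: float | None
    d0: pd.Series  # ppm, indexed by residue id
    d0_stderr: pd.Series
    residuals: np.ndarray  # (R, L) ppm, model - data
    protein: float  # mM
    ligand: np.ndarray  # mM
    success: bool
    n_eval: int
    chisqr: float
    kd_bootstrap_sd: float | None = None


def combined_csp(ddh, ddn, weights: CSPWeights = DEFAULT_WEIGHTS):
    """Weighted combined 1H/15N chemical shift perturbation in ppm.

    Non-negative and symmetric in the sign of either shift change.
    """
    ddh = np.asarray(ddh, dtype=float)
    ddn = np.asarray(ddn, dtype=float)
    out = np.sqrt((ddh * weights.w_h) ** 2 + (ddn * weights.w_n) ** 2)
    return float(out) if out.ndim == 0 else out


def isotherm_csp(protein, ligand, kd, d0):
    """One-site binding isotherm with ligand depletion.

    Returns the combined CSP (ppm) at ligand concentration ``ligand`` for a
    residue saturating at ``d0``; exactly d0 * [bound protein fraction].
    Zero at L = 0, monotone increasing in L, approaching d0 as L -> inf.
    All concentrations in mM.
    """
    ligand = np.asarray(ligand, dtype=float)
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if np.any(ligand < 0):
        raise ValueError("ligand concentrations must be non-negative")
    s = protein + ligand + kd
    disc = np.maximum(s**2 - 4.0 * protein * ligand, 0.0)
    out = d0 * (s - np.sqrt(disc)) / (2.0 * protein)
    return float(out) if out.ndim == 0 else out


def select_binders(
    tset: TitrationSet,
    at_ligand: float = 2.0,
    threshold: float = 0.05,
    weights: CSPWeights = DEFAULT_WEIGHTS,
) -> list:
    """Residues whose combined CSP at ``at_ligand`` strictly exceeds ``threshold``.

    The inequality is strict: a residue sitting exactly at the cutoff is
    excluded.  ``at_ligand`` must be a point of the titration grid.
    """
    matches = np.flatnonzero(np.isclose(tset.ligand, at_ligand))
    if matches.size == 0:
        raise ValueError(
            f"ligand point {at_ligand} mM is not on the titration grid "
            f"{tset.ligand.tolist()}"
        )
    col = tset.csp(weights)[:, matches[0]]
    return [r for r, c in zip(tset.residues, col) if c > threshold]


def _model_matrix(params, protein, ligand, binders):
    kd = params["kd"].value
    rows = [
        isotherm_csp(protein, ligand, kd, params[f"d0_{i}"].value)
        for i in range(len(binders))
    ]
    return np.vstack(rows)


def fit_global(
    tset: TitrationSet,
    binders: list,
    init: dict | None = None,
    weights: CSPWeights = DEFAULT_WEIGHTS,
    bootstrap: int = 0,
    seed: int | None = None,
) -> BindingFitResult:
    """Simultaneous one-site fit of all binder residues.

    One shared K_D and one d0 per binder are fitted by nonlinear least
    squares on the raw combined CSPs.  Without ``init`` the fit multi-starts
    from a log-spaced K_D grid (0.01-100 mM) and keeps the lowest-cost
    solution.  Standard errors come from the Jacobian covariance at the
    optimum; ``bootstrap`` > 0 adds a seeded residual bootstrap of K_D.
    """
    binders = list(binders)
    if not binders:
        raise ValueError("need at least one binder residue")
    if tset.ligand.size < 3:
        raise ValueError("need at least 3 ligand points")
    n_points = tset.ligand.size * len(binders)
    n_params = 1 + len(binders)
    if n_points < n_params:
        raise ValueError(
            f"underdetermined fit: {n_points} points for {n_params} parameters"
        )
    res_index = {r: i for i, r in enumerate(tset.residues)}
    try:
        rows = [res_index[r] for r in binders]
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]} not in titration set") from exc
    data = tset.csp(weights)[rows, :]

    def residual(params):
        return (_model_matrix(params, tset.protein, tset.ligand, binders) - data).ravel()

    d0_guess = data.max(axis=1)
    if init is not None:
        kd_starts = [float(init["kd"])]
    else:
        kd_starts = list(np.logspace(-2, 2, 7))
    best = None
    for kd0 in kd_starts:
        params = lmfit.Parameters()
        params.add("kd", value=kd0, min=1e-6)
        for i, g in enumerate(d0_guess):
            if init is not None and "d0" in init:
                g = float(init["d0"].get(binders[i], g))
            params.add(f"d0_{i}", value=max(g, 1e-6), min=0.0)
        out = lmfit.minimize(residual, params, method="leastsq")
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise FitError("global K_D fit did not converge", best=best)

    kd = float(best.params["kd"].value)
    kd_err = best.params["kd"].stderr
    d0 = pd.Series(
        [best.params[f"d0_{i}"].value for i in range(len(binders))], index=binders
    )
    d0_err = pd.Series(
        [
            best.params[f"d0_{i}"].stderr
            if best.params[f"d0_{i}"].stderr is not None
            else np.nan
            for i in range(len(binders))
        ],
        index=binders,
    )
    model = _model_matrix(best.params, tset.protein, tset.ligand, binders)
    residuals = model - data

    kd_boot_sd = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        flat_res = residuals.ravel()
        boots = []
        for _ in range(bootstrap):
            fake = model.ravel() + rng.choice(flat_res, size=flat_res.size)
            fake = fake.reshape(model.shape)

            def boot_residual(params, fake=fake):
                return (
                    _model_matrix(params, tset.protein, tset.ligand, binders) - fake
                ).ravel()

            params = lmfit.Parameters()
            params.add("kd", value=kd, min=1e-6)
            for i in range(len(binders)):
                params.add(f"d0_{i}", value=float(d0.iloc[i]), min=0.0)
            bout = lmfit.minimize(boot_residual, params, method="leastsq")
            if bout.success:
                boots.append(bout.params["kd"].value)
        if len(boots) > 1:
            kd_boot_sd = float(np.std(boots, ddof=1))

    return BindingFitResult(
        kd=kd,
        kd_stderr=float(kd_err) if kd_err is not None else None,
        d0=d0,
        d0_stderr=d0_err,
        residuals=residuals,
        protein=tset.protein,
        ligand=tset.ligand.copy(),
        success=bool(best.success),
        n_eval=int(best.nfev),
        chisqr=float(best.chisqr),
        kd_bootstrap_sd=kd_boot_sd,
    )


def normalize_for_plot(
    result: BindingFitResult,
    tset: TitrationSet,
    weights: CSPWeights = DEFAULT_WEIGHTS,
    dense_points: int = 200,
) -> dict:
    """Saturation-normalised averaged curve for display.

    Per ligand point: mean over binders of CSP / d0_r with the population
    standard deviation as error bar, plus the fitted curve (normalised, so
    it tends to 1 at saturation) on a dense ligand grid.  Binders with a
    fitted d0 of zero are excluded with a warning.
    """
    keep = result.d0[result.d0 > 0]
    dropped = [r for r in result.d0.index if r not in keep.index]
    if dropped:
        log.warning("excluding binders with zero fitted d0: %s", dropped)
    if keep.empty:
        raise ValueError("no binders with positive fitted saturation CSP")
    res_index = {r: i for i, r in enumerate(tset.residues)}
    rows = [res_index[r] for r in keep.index]
    data = tset.csp(weights)[rows, :]
    norm = data / keep.to_numpy()[:, None]
    dense_l = np.linspace(0.0, float(tset.ligand.max()), dense_points)
    curve = isotherm_csp(result.protein, dense_l, result.kd, 1.0)
    return {
        "ligand": tset.ligand.copy(),
        "mean": norm.mean(axis=0),
        "sd": norm.std(axis=0, ddof=0),
        "curve_ligand": dense_l,
        "curve": curve,
    }


def read_titration_table(path, protein: float) -> TitrationSet:
    """Read a tab-separated table `residue ligand_mM ddH_ppm ddN_ppm`."""
    table = pd.read_csv(path, sep="\t")
    required = {"residue", "ligand_mM", "ddH_ppm", "ddN_ppm"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(table.columns))}"
        )
    ligand = np.sort(table["ligand_mM"].unique())
    residues = table["residue"].unique()
    ddh = np.zeros((residues.size, ligand.size))
    ddn = np.zeros_like(ddh)
    pivot_h = table.pivot(index="residue", columns="ligand_mM", values="ddH_ppm")
    pivot_n = table.pivot(index="residue", columns="ligand_mM", values="ddN_ppm")
    if pivot_h.isna().any().any() or pivot_n.isna().any().any():
        raise ValueError(f"{path}: residues do not share a common ligand grid")
    ddh = pivot_h.loc[residues, ligand].to_numpy()
    ddn = pivot_n.loc[residues, ligand].to_numpy()
    return TitrationSet(protein=protein, ligand=ligand, residues=residues, ddh=ddh, ddn=ddn)


def write_titration_table(tset: TitrationSet, path) -> None:
    rows = []
    for i, r in enumerate(tset.residues):
        for j, l in enumerate(tset.ligand):
            rows.append((r, l, tset.ddh[i, j], tset.ddn[i, j]))
    pd.DataFrame(rows, columns=["residue", "ligand_mM", "ddH_ppm", "ddN_ppm"]).to_csv(
        path, sep="\t", index=False
    )
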
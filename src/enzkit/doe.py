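"""Screening and response-surface designs with second-order model fitting.

Three design generators (12-run Plackett–Burman screening, rotatable
central-composite, Box–Behnken), a Plackett–Burman main-effect screen with
dummy-column pseudo-error, and a statsmodels-style :class:`ResponseSurface`
model whose :meth:`ResponseSurface.fit` returns the full quadratic
coefficients (natural and coded units) together with a Design-Expert-style
ANOVA: block, model, per-term (partial SS), residual split into lack-of-fit
and replicate pure error, and the corrected total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .exceptions import DegenerateDataError, EnzkitError, InsufficientDataError

# First row of the cyclic generator for the 12-run Plackett-Burman design
_PB12_GENERATOR = np.array([1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1])


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded-to-natural mapping."""

    name: str
    symbol: str  # e.g. "A"
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if self.half_range <= 0:
            raise EnzkitError("half-range must be positive")

    def to_natural(self, coded):
        return self.center + np.asarray(coded, dtype=float) * self.half_range

    def to_coded(self, natural):
        return (np.asarray(natural, dtype=float) - self.center) / self.half_range


@dataclass
class DesignMatrix:
    """Runs of a designed experiment in coded and natural units."""

    kind: str  # plackett_burman | central_composite | box_behnken | custom
    coded: np.ndarray  # runs × factors
    factors: list[FactorSpec] | None = None
    blocks: np.ndarray | None = None  # integer block labels, or None
    run_ids: np.ndarray | None = None
    dummy_columns: list[int] = field(default_factory=list)  # PB columns with no factor

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.run_ids is None:
            self.run_ids = np.arange(1, self.coded.shape[0] + 1)
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def natural(self) -> np.ndarray:
        if self.factors is None:
            raise EnzkitError("no factor specifications attached")
        return np.column_stack(
            [f.to_natural(self.coded[:, i]) for i, f in enumerate(self.factors)]
        )

    def to_frame(self) -> pd.DataFrame:
        if self.factors is not None:
            df = pd.DataFrame(self.natural, columns=[f.name for f in self.factors])
        else:
            df = pd.DataFrame(self.coded, columns=[f"x{i+1}" for i in range(self.coded.shape[1])])
        df.insert(0, "run", self.run_ids)
        if self.blocks is not None:
            df["block"] = self.blocks
        return df


def plackett_burman_design(n_factors: int, factors: list[FactorSpec] | None = None) -> DesignMatrix:
    """Standard 12-run Plackett–Burman screening design for up to 11 factors.

    The matrix is built from the cyclic generator row plus a final all-minus
    run; columns beyond ``n_factors`` remain as dummy columns whose apparent
    effects estimate the experimental error.
    """
    if not 1 <= n_factors <= 11:
        raise EnzkitError("design too small: a 12-run Plackett-Burman supports at most 11 factors")
    rows = [np.roll(_PB12_GENERATOR, i) for i in range(11)]
    mat = np.vstack(rows + [-np.ones(11, dtype=int)]).astype(float)
    return DesignMatrix(
        kind="plackett_burman",
        coded=mat,
        factors=factors,
        dummy_columns=list(range(n_factors, 11)),
    )


@dataclass
class PBEffect:
    column: int
    name: str
    effect: float
    t: float | None
    p: float | None
    significant: bool | None


def pb_effect_screen(
    design: DesignMatrix, responses, alpha: float = 0.05, method: str = "dummy"
) -> list[PBEffect]:
    """Main effects of a Plackett–Burman screen, ranked by |t|.

    effect_j = mean(y | x_j = +1) − mean(y | x_j = −1).  The error variance
    comes from the dummy-column effects (``method="dummy"``, Minitab-style) or
    from Lenth's pseudo standard error (``method="lenth"``).  With no dummy
    columns available the effects are returned unranked by significance, with
    ``t``/``p`` set to None.
    """
    y = np.asarray(responses, dtype=float)
    if y.size != design.n_runs:
        raise EnzkitError(f"expected {design.n_runs} responses, got {y.size}")
    X = design.coded
    effects = np.array([y[X[:, j] > 0].mean() - y[X[:, j] < 0].mean() for j in range(X.shape[1])])
    names = []
    for j in range(X.shape[1]):
        if design.factors is not None and j < len(design.factors):
            names.append(design.factors[j].name)
        elif j in design.dummy_columns:
            names.append(f"dummy{j+1}")
        else:
            names.append(f"x{j+1}")
    real = [j for j in range(X.shape[1]) if j not in design.dummy_columns]
    if method == "lenth":
        s0 = 1.5 * np.median(np.abs(effects))
        pse = 1.5 * np.median(np.abs(effects[np.abs(effects) < 2.5 * s0]))
        se, df = pse, max(round(len(effects) / 3), 1)
    elif design.dummy_columns:
        dummy_eff = effects[design.dummy_columns]
        se = float(np.sqrt(np.mean(dummy_eff**2)))
        df = len(design.dummy_columns)
    else:
        import warnings

        warnings.warn("no dummy columns and no replicates: effects without significance flags", stacklevel=2)
        out = [PBEffect(j, names[j], float(effects[j]), None, None, None) for j in real]
        return sorted(out, key=lambda e: -abs(e.effect))
    out = []
    for j in real:
        if se == 0:
            t = 0.0 if effects[j] == 0 else float("inf")
        else:
            t = effects[j] / se
        p = float(2 * (1 - stats.t.cdf(abs(t), df))) if np.isfinite(t) else 0.0
        out.append(PBEffect(j, names[j], float(effects[j]), float(t), p, p < alpha))
    return sorted(out, key=lambda e: -abs(e.t))


def central_composite_design(
    factors: list[FactorSpec],
    n_center: int = 6,
    blocks: bool = False,
    center_split: tuple[int, int] = (4, 2),
) -> DesignMatrix:
    """Rotatable central composite design for 3 factors (20 runs by default).

    8 factorial corners at ±1, 6 axial points at ±α with α = 8^(1/4) ≈ 1.682
    (rotatability), and ``n_center`` center replicates.  With ``blocks=True``
    the runs split into an orthogonal two-block layout: factorial corners plus
    ``center_split[0]`` centers, then axial points plus ``center_split[1]``
    centers.
    """
    k = len(factors)
    if k != 3:
        raise EnzkitError("this central composite generator covers the 3-factor case")
    alpha = 8.0 ** 0.25
    corners = np.array([[i, j, l] for i in (-1, 1) for j in (-1, 1) for l in (-1, 1)], dtype=float)
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    if blocks:
        n1, n2 = center_split
        if n1 + n2 != n_center:
            raise EnzkitError("center_split must sum to n_center")
        coded = np.vstack([corners, np.zeros((n1, k)), axial, np.zeros((n2, k))])
        blk = np.array([1] * (8 + n1) + [2] * (2 * k + n2))
    else:
        coded = np.vstack([corners, axial, np.zeros((n_center, k))])
        blk = None
    return DesignMatrix(kind="central_composite", coded=coded, factors=factors, blocks=blk)


def box_behnken_design(factors: list[FactorSpec], n_center: int = 3) -> DesignMatrix:
    """Standard 3-factor Box–Behnken design: 12 edge midpoints + center replicates."""
    if len(factors) != 3:
        raise EnzkitError("this Box-Behnken generator covers the 3-factor case")
    runs = []
    for zero in range(3):
        pair = [i for i in range(3) if i != zero]
        for u in (-1, 1):
            for v in (-1, 1):
                row = [0.0, 0.0, 0.0]
                row[pair[0]], row[pair[1]] = u, v
                runs.append(row)
    coded = np.vstack([np.array(runs), np.zeros((n_center, 3))])
    return DesignMatrix(kind="box_behnken", coded=coded, factors=factors)


def _quadratic_columns(x: np.ndarray, symbols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Full second-order expansion: linear, pairwise interactions, squares."""
    k = x.shape[1]
    cols, names = [], []
    for i in range(k):
        cols.append(x[:, i])
        names.append(symbols[i])
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(x[:, i] * x[:, j])
            names.append(symbols[i] + symbols[j])
    for i in range(k):
        cols.append(x[:, i] ** 2)
        names.append(symbols[i] + "^2")
    return np.column_stack(cols), names


@dataclass
class QuadraticModelResults:
    """Fitted second-order response surface with its ANOVA decomposition."""

    factors: list[FactorSpec]
    coef_natural: dict[str, float]  # includes "Intercept"
    coef_coded: dict[str, float]
    block_effect: float | None
    anova: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray
    coef_se_natural: dict[str, float] = field(default_factory=dict)

    @property
    def model_f(self) -> float:
        return float(self.anova.loc["Model", "F"])

    @property
    def lack_of_fit_f(self) -> float | None:
        v = self.anova.loc["Lack of fit", "F"] if "Lack of fit" in self.anova.index else None
        return None if v is None or np.isnan(v) else float(v)

    def predict(self, natural_points) -> np.ndarray:
        """Block-averaged prediction at natural-unit factor settings."""
        x = np.atleast_2d(np.asarray(natural_points, dtype=float))
        symbols = [f.symbol for f in self.factors]
        cols, names = _quadratic_columns(x, symbols)
        y = np.full(x.shape[0], self.coef_natural["Intercept"])
        for c, n in zip(cols.T, names):
            y = y + self.coef_natural[n] * c
        return y

    def summary(self) -> str:
        eq = " + ".join(
            [f"{self.coef_natural['Intercept']:.5g}"]
            + [f"{v:+.5g}·{k}" for k, v in self.coef_natural.items() if k != "Intercept"]
        )
        return (
            "Second-order response surface (natural units)\n"
            f"y = {eq}\n\n"
            f"R² = {self.r_squared:.4f}, adj. R² = {self.adj_r_squared:.4f}\n\n"
            + self.anova.to_string(float_format=lambda v: f"{v:.4f}")
        )


class ResponseSurface:
    """OLS second-order polynomial model over a designed experiment.

    Parameters
    ----------
    design : DesignMatrix
        Must carry factor specifications (for the natural-unit equation).
    responses : array-like
        One response per run.
    include_block : bool
        Add a fixed block effect (design must carry block labels).
    """

    def __init__(self, design: DesignMatrix, responses, include_block: bool = False):
        y = np.asarray(responses, dtype=float)
        if y.size != design.n_runs:
            raise EnzkitError(f"expected {design.n_runs} responses, got {y.size}")
        if design.factors is None:
            raise EnzkitError("design must carry factor specifications")
        if include_block and design.blocks is None:
            raise EnzkitError("include_block requires block labels on the design")
        self.design = design
        self.y = y
        self.include_block = include_block

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, factors: list[FactorSpec], response: str = "response"
    ) -> "ResponseSurface":
        """Build from a table with natural-unit factor columns and a response column."""
        if response not in df.columns:
            raise EnzkitError(f"schema error: missing column {response!r}")
        coded = np.column_stack([f.to_coded(df[f.name].to_numpy()) for f in factors])
        blocks = df["block"].to_numpy() if "block" in df.columns else None
        design = DesignMatrix(kind="custom", coded=coded, factors=factors, blocks=blocks)
        return cls(design, df[response].to_numpy(), include_block=blocks is not None)

    def _design_matrices(self):
        symbols = [f.symbol for f in self.design.factors]
        Xc, names = _quadratic_columns(self.design.coded, symbols)
        Xn, _ = _quadratic_columns(self.design.natural, symbols)
        return Xc, Xn, names

    def fit(self) -> QuadraticModelResults:
        y = self.y
        n = y.size
        Xc, Xn, names = self._design_matrices()
        p = Xc.shape[1]
        if n < p + 1 + (1 if self.include_block else 0):
            raise InsufficientDataError("more coefficients than runs")
        blk_col = None
        if self.include_block:
            labels = self.design.blocks
            uniq = np.unique(labels)
            if uniq.size != 2:
                raise EnzkitError("exactly two blocks supported")
            blk_col = (labels == uniq[1]).astype(float)

        def lstsq_sse(X):
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                raise DegenerateDataError("singular design")
            r = y - X @ beta
            return beta, float(r @ r)

        ones = np.ones((n, 1))
        full_cols = [ones] + ([blk_col[:, None]] if blk_col is not None else []) + [Xc]
        X_full = np.hstack(full_cols)
        beta_c, sse_full = lstsq_sse(X_full)

        ss_total = float(np.sum((y - y.mean()) ** 2))
        if blk_col is not None:
            _, sse_block_only = lstsq_sse(np.hstack([ones, blk_col[:, None]]))
            ss_block = ss_total - sse_block_only
        else:
            ss_block = 0.0
        ss_model = ss_total - ss_block - sse_full
        df_block = 1 if blk_col is not None else 0
        df_model = p
        df_resid = n - 1 - df_block - df_model
        ms_model = ss_model / df_model
        ms_resid = sse_full / df_resid if df_resid > 0 else np.nan
        f_model = ms_model / ms_resid if df_resid > 0 else np.nan
        p_model = float(1 - stats.f.cdf(f_model, df_model, df_resid)) if df_resid > 0 else np.nan

        rows = []
        if blk_col is not None:
            rows.append(("Block", ss_block, df_block, ss_block / df_block, np.nan, np.nan))
        rows.append(("Model", ss_model, df_model, ms_model, f_model, p_model))
        # Partial (drop-one-term) SS on the coded scale
        offset = 1 + df_block
        for j, name in enumerate(names):
            keep = [i for i in range(X_full.shape[1]) if i != offset + j]
            _, sse_red = lstsq_sse(X_full[:, keep])
            ss_j = sse_red - sse_full
            f_j = ss_j / ms_resid if df_resid > 0 else np.nan
            p_j = float(1 - stats.f.cdf(f_j, 1, df_resid)) if df_resid > 0 else np.nan
            rows.append((name, ss_j, 1, ss_j, f_j, p_j))
        rows.append(("Residual", sse_full, df_resid, ms_resid, np.nan, np.nan))

        # Lack of fit vs pure error from replicate groups (within block)
        groups: dict[tuple, list[int]] = {}
        for i in range(n):
            key = tuple(np.round(self.design.coded[i], 10))
            if blk_col is not None:
                key = key + (int(blk_col[i]),)
            groups.setdefault(key, []).append(i)
        ss_pe = 0.0
        df_pe = 0
        for idx in groups.values():
            if len(idx) > 1:
                g = y[list(idx)]
                ss_pe += float(np.sum((g - g.mean()) ** 2))
                df_pe += len(idx) - 1
        if df_pe > 0 and df_resid > df_pe:
            ss_lof = sse_full - ss_pe
            df_lof = df_resid - df_pe
            ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
            if ms_pe > 0:
                f_lof = ms_lof / ms_pe
                p_lof = float(1 - stats.f.cdf(f_lof, df_lof, df_pe))
            else:  # exact replicates (e.g. noiseless synthetic data)
                f_lof, p_lof = np.nan, np.nan
            rows.append(("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
            rows.append(("Pure error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
        rows.append(("Cor total", ss_total, n - 1, np.nan, np.nan, np.nan))
        anova = pd.DataFrame(
            rows, columns=["source", "SS", "df", "MS", "F", "p"]
        ).set_index("source")

        # Natural-unit coefficients: same fit on the natural-scale expansion
        full_nat = [ones] + ([blk_col[:, None]] if blk_col is not None else []) + [Xn]
        X_nat = np.hstack(full_nat)
        beta_n, _ = lstsq_sse(X_nat)
        se_n = np.sqrt(np.diag(np.linalg.inv(X_nat.T @ X_nat)) * ms_resid) if df_resid > 0 else np.full(X_nat.shape[1], np.nan)
        block_eff = None
        if blk_col is not None:
            block_eff = float(beta_n[1])
            icept_n = float(beta_n[0] + block_eff * blk_col.mean())
            icept_c = float(beta_c[0] + beta_c[1] * blk_col.mean())
            coefs_n = beta_n[2:]
            coefs_c = beta_c[2:]
            ses_n = se_n[2:]
        else:
            icept_n, icept_c = float(beta_n[0]), float(beta_c[0])
            coefs_n, coefs_c = beta_n[1:], beta_c[1:]
            ses_n = se_n[1:]
        coef_natural = {"Intercept": icept_n, **{nm: float(v) for nm, v in zip(names, coefs_n)}}
        coef_coded = {"Intercept": icept_c, **{nm: float(v) for nm, v in zip(names, coefs_c)}}
        coef_se_natural = {"Intercept": float(se_n[0]), **{nm: float(v) for nm, v in zip(names, ses_n)}}

        fitted = X_full @ beta_c
        resid = y - fitted
        r2 = 1 - sse_full / (ss_total - ss_block) if ss_total > ss_block else 1.0
        adj = 1 - (1 - r2) * (n - 1 - df_block) / df_resid if df_resid > 0 else np.nan
        return QuadraticModelResults(
            factors=list(self.design.factors),
            coef_natural=coef_natural,
            coef_coded=coef_coded,
            block_effect=block_eff,
            anova=anova,
            r_squared=float(r2),
            adj_r_squared=float(adj),
            fitted=fitted,
            residuals=resid,
            coef_se_natural=coef_se_natural,
        )


def fit_response_surface(
    design: DesignMatrix, responses, include_block: bool = False
) -> QuadraticModelResults:
    """Functional façade over :class:`ResponseSurface`."""
    return ResponseSurface(design, responses, include_block=include_block).fit()


def quadratic_model_from_coefficients(
    factors: list[FactorSpec], coef_natural: dict[str, float]
) -> QuadraticModelResults:
    """Wrap externally given natural-unit coefficients for prediction/optimization."""
    empty = pd.DataFrame(columns=["SS", "df", "MS", "F", "p"])
    return QuadraticModelResults(
        factors=list(factors),
        coef_natural=dict(coef_natural),
        coef_coded={},
        block_effect=None,
        anova=empty,
        r_squared=float("nan"),
        adj_r_squared=float("nan"),
        fitted=np.array([]),
        residuals=np.array([]),
    )


def optimize_response(
    model: QuadraticModelResults,
    bounds: list[tuple[float, float]],
    grid_points: int = 50,
) -> tuple[np.ndarray, float]:
    """Maximize the fitted quadratic over a box of natural-unit bounds.

    The stationary point of the quadratic is solved in closed form; if it is a
    maximum inside the bounds it is returned directly.  Otherwise the box is
    scanned on a dense grid (``grid_points`` per axis) and the best cell is
    refined by bounded local ascent.
    """
    k = len(model.factors)
    symbols = [f.symbol for f in model.factors]
    b = np.array([model.coef_natural[s] for s in symbols])
    Bmat = np.zeros((k, k))
    for i in range(k):
        Bmat[i, i] = model.coef_natural[symbols[i] + "^2"]
        for j in range(i + 1, k):
            key = symbols[i] + symbols[j]
            Bmat[i, j] = Bmat[j, i] = model.coef_natural.get(key, 0.0) / 2.0
    # stationary point: grad = b + 2·B·x = 0
    try:
        x_st = np.linalg.solve(2 * Bmat, -b)
        eig = np.linalg.eigvalsh(Bmat)
        in_bounds = all(lo <= xi <= hi for xi, (lo, hi) in zip(x_st, bounds))
        if in_bounds and np.all(eig < 0):
            return x_st, float(model.predict(x_st)[0])
    except np.linalg.LinAlgError:
        pass
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = model.predict(pts)
    x0 = pts[int(np.argmax(vals))]
    res = minimize(
        lambda x: -model.predict(x)[0], x0, bounds=bounds, method="L-BFGS-B"
    )
    x_best = res.x if -res.fun >= vals.max() else x0
    return x_best, float(model.predict(x_best)[0])
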
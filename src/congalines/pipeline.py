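"""End-to-end inference: radius scan, significance ranges, validation harness.

The observed-vs-predicted procedure for one surface:

1. count the observed three-point alignments for r from 5 to 50 mm at 1 mm
   increments (theta fixed, default 30 deg);
2. fit CSR and Thomas backgrounds to the surface point pattern (once — the
   background is a property of the surface, not of the search radius);
3. keep the model with the higher Diggle GOF p_d;
4. compute the expected chance-alignment count under that model per r;
5. evaluate the Poisson tail probability of the observed count per r;
6. report maximal contiguous r ranges in which significantly more (or fewer)
   alignments are found than predicted (alpha = 0.05, per-radius, no
   multiple-testing correction by default — a Bonferroni flag is available).

``validate_analytic`` is the numerical check that the analytic expectations
match Monte-Carlo means over simulated backgrounds across parameter grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import AlignmentParams, count_alignments
from .fitting import ModelSelection, select_model
from .generators import CsrParams, ThomasParams, _simulate_background
from .nullmodels import (
    edge_allowance,
    expected_count,
    poisson_tail,
)
from .surfaces import SurfaceMap, Window

__all__ = [
    "ScanRow",
    "SignificanceScan",
    "ValidationRow",
    "ValidationReport",
    "scan",
    "significance_ranges",
    "validate_analytic",
    "run_surface_report",
    "csr_validation_grid",
    "thomas_validation_grid",
    "poisson_histogram_pvalue",
]


@dataclass(frozen=True)
class ScanRow:
    """One radius of the significance scan."""

    r: float  # metres
    observed: int
    model: str
    expected: float
    p_upper: float
    p_lower: float
    direction: str
    significant: bool

    @property
    def r_mm(self) -> float:
        return round(self.r * 1000.0, 9)


@dataclass(frozen=True)
class SignificanceScan:
    """Per-radius table plus derived significance ranges for one surface."""

    rows: tuple
    theta_deg: float
    alpha: float
    selection: ModelSelection | None
    ranges_more: tuple  # ((r_lo_mm, r_hi_mm), ...) closed intervals
    ranges_fewer: tuple

    def range_str(self, direction: str) -> str:
        ranges = self.ranges_more if direction == "more" else self.ranges_fewer
        if not ranges:
            return "N/A"
        return ", ".join(f"{lo:g}-{hi:g}" for lo, hi in ranges)


def significance_ranges(rows, alpha: float) -> tuple:
    """Maximal contiguous runs of significant radii, split by direction.

    Returns (ranges_more, ranges_fewer), each a tuple of closed (lo, hi)
    intervals in millimetres whose endpoints are grid values.
    """
    out = {"more": [], "fewer": []}
    run_dir, run_start, run_end = None, None, None
    for row in rows:
        d = row.direction if row.significant else None
        if d == run_dir and d is not None:
            run_end = row.r_mm
        else:
            if run_dir is not None:
                out[run_dir].append((run_start, run_end))
            run_dir, run_start, run_end = d, row.r_mm, row.r_mm
    if run_dir is not None:
        out[run_dir].append((run_start, run_end))
    return tuple(out["more"]), tuple(out["fewer"])


def scan(
    surface: SurfaceMap,
    theta_deg: float = 30.0,
    r_min: float = 0.005,
    r_max: float = 0.050,
    step: float = 0.001,
    alpha: float = 0.05,
    seed=None,
    m_gof: int = 99,
    selection: ModelSelection | None = None,
    bonferroni: bool = False,
) -> SignificanceScan:
    """Observed-vs-predicted significance scan over the radius grid.

    ``selection`` may be supplied to reuse a precomputed background fit;
    otherwise :func:`congalines.fitting.select_model` is run once.
    ``bonferroni=True`` divides alpha by the number of radii.
    """
    r_grid = np.arange(r_min, r_max + step / 2, step)
    if surface.n == 0:
        rows = tuple(
            ScanRow(float(r), 0, "csr", 0.0, 1.0, 1.0, "fewer", False)
            for r in r_grid
        )
        return SignificanceScan(rows, theta_deg, alpha, None, (), ())

    if selection is None:
        selection = select_model(surface, seed=seed, m=m_gof)
    model = selection.selected_params
    A = surface.window.area
    alpha_eff = alpha / len(r_grid) if bonferroni else alpha

    rows = []
    for r in r_grid:
        res = count_alignments(surface, AlignmentParams(float(r), theta_deg))
        E = expected_count(model, A, float(r), theta_deg).E
        tail = poisson_tail(res.count, E)
        sig = (
            tail.p_upper < alpha_eff
            if tail.direction == "more"
            else tail.p_lower < alpha_eff
        )
        rows.append(
            ScanRow(
                r=float(r),
                observed=res.count,
                model=selection.selected,
                expected=E,
                p_upper=tail.p_upper,
                p_lower=tail.p_lower,
                direction=tail.direction,
                significant=bool(sig),
            )
        )
    rows = tuple(rows)
    more, fewer = significance_ranges(rows, alpha_eff)
    return SignificanceScan(rows, theta_deg, alpha, selection, more, fewer)


# ---------------------------------------------------------------------------
# analytic-vs-numeric validation


@dataclass(frozen=True)
class ValidationRow:
    """One grid point of the analytic-vs-numeric comparison."""

    model: str
    params: dict
    r: float
    theta_deg: float
    analytic_E: float
    mc_mean: float
    mc_se: float
    n_sims: int
    z: float  # |analytic - mc| in SE units
    edge_rel: float  # perimeter * r / A
    ok: bool  # within 3 SE + edge allowance


@dataclass(frozen=True)
class ValidationReport:
    rows: tuple

    @property
    def all_ok(self) -> bool:
        return all(row.ok for row in self.rows)


def csr_validation_grid(
    r_mm=(10, 12, 15, 20), theta=(20, 25, 30, 45), lam=(10, 50, 100, 150)
):
    """Full product grid of CSR validation cells (r x theta x lambda)."""
    return [
        (CsrParams(la), r / 1000.0, th)
        for r in r_mm
        for th in theta
        for la in lam
    ]


def thomas_validation_grid(
    kappa=(10, 75, 150, 200),
    mu=(2, 3, 4, 6),
    sigma_mm=(20, 45, 75, 120),
    controls=(55.0, 3.0, 45.0),
    r_mm: float = 15.0,
    theta: float = 30.0,
):
    """Thomas validation cells, one parameter varied at a time about controls
    (kappa = 55 m^-2, mu = 3, sigma = 45 mm)."""
    k0, m0, s0 = controls
    cells = []
    for k in kappa:
        cells.append((ThomasParams(k, m0, s0 / 1000.0), r_mm / 1000.0, theta))
    for m in mu:
        cells.append((ThomasParams(k0, m, s0 / 1000.0), r_mm / 1000.0, theta))
    for s in sigma_mm:
        cells.append((ThomasParams(k0, m0, s / 1000.0), r_mm / 1000.0, theta))
    return cells


def _mc_counts(model, window, r, theta_deg, n_sims, ss) -> np.ndarray:
    params = AlignmentParams(r, theta_deg)
    counts = np.empty(n_sims, dtype=int)
    for i, child in enumerate(ss.spawn(n_sims)):
        pat = _simulate_background(model, window, np.random.default_rng(child))
        counts[i] = count_alignments(pat, params).count
    return counts


def validate_analytic(
    cells, window: Window, n_sims: int = 500, seed=None
) -> ValidationReport:
    """Compare analytic expectations to Monte-Carlo means per grid cell.

    A cell passes when |analytic E - MC mean| <= 3 SE + (perimeter r / A) E,
    the second term being the uncorrected-edge allowance. The SE guards the
    degenerate all-zero cell with the Poisson floor sqrt(max(mean, E)/n).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence
    ) else seed
    rows = []
    for (model, r, theta_deg), child in zip(cells, ss.spawn(len(cells))):
        E = expected_count(model, window.area, r, theta_deg).E
        counts = _mc_counts(model, window, r, theta_deg, n_sims, child)
        mean = float(counts.mean())
        se = float(counts.std(ddof=1) / np.sqrt(n_sims)) if n_sims > 1 else 0.0
        se = max(se, float(np.sqrt(max(mean, E) / n_sims)))
        edge_rel = edge_allowance(window, r)
        z = abs(E - mean) / se if se > 0 else 0.0
        ok = abs(E - mean) <= 3.0 * se + edge_rel * E
        name = "csr" if isinstance(model, CsrParams) else "thomas"
        params = (
            {"lam": model.lam}
            if name == "csr"
            else {"kappa": model.kappa, "mu": model.mu, "sigma": model.sigma}
        )
        rows.append(
            ValidationRow(
                model=name,
                params=params,
                r=r,
                theta_deg=theta_deg,
                analytic_E=E,
                mc_mean=mean,
                mc_se=se,
                n_sims=n_sims,
                z=float(z),
                edge_rel=float(edge_rel),
                ok=bool(ok),
            )
        )
    return ValidationReport(tuple(rows))


def run_surface_report(
    points_path,
    window_path,
    discs_path=None,
    mask_path=None,
    config=None,
    out_dir="results",
    variants: bool = False,
) -> dict:
    """Read a surface from disk, run the significance scan, write a report.

    With ``variants=True`` (and the needed inputs present) all four
    preprocessing variants are scanned: raw, retrodeformed, masked, and
    retrodeformed + masked — the standard sensitivity set for a surface with
    strain discs and eroded patches.

    Writes per variant: ``scan_<variant>.tsv``, ``ranges_<variant>.json``,
    ``fit_<variant>.json``; plus a ``run_log.json`` with seed/config/version.
    Returns the SignificanceScan objects keyed by variant name.
    """
    from pathlib import Path

    from . import io as cio
    from .surfaces import estimate_strain, mask_holes, retrodeform

    cfg = config or cio.RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = cio.read_window(window_path)
    surface = cio.read_point_map(points_path, window=window)
    discs = cio.read_discs(discs_path) if discs_path else None
    if discs is not None:
        surface = SurfaceMap(
            points=surface.points, window=surface.window, marks=surface.marks,
            discs=discs,
        )
    mask_window = cio.read_window(mask_path) if mask_path else None
    mask_polys = (
        [mask_window.exterior] + list(mask_window.holes) if mask_window else None
    )

    def build(retro: bool, masked: bool):
        s = surface
        if retro:
            s = retrodeform(s, estimate_strain(s.discs))
        if masked:
            s = mask_holes(s, mask_polys)
        return s

    wanted = {"raw": (False, False)}
    if variants:
        if discs is not None:
            wanted["retrodeformed"] = (True, False)
        if mask_polys is not None:
            wanted["masked"] = (False, True)
        if discs is not None and mask_polys is not None:
            wanted["retrodeformed_masked"] = (True, True)

    ss = np.random.SeedSequence(cfg.seed)
    results = {}
    for (name, (retro, masked)), child in zip(wanted.items(), ss.spawn(len(wanted))):
        surf = build(retro, masked)
        res = scan(
            surf,
            theta_deg=cfg.theta_deg,
            r_min=cfg.r_min_mm / 1000.0,
            r_max=cfg.r_max_mm / 1000.0,
            step=cfg.step_mm / 1000.0,
            alpha=cfg.alpha,
            seed=child,
            m_gof=cfg.gof_m,
            bonferroni=cfg.bonferroni,
        )
        results[name] = res
        cio.write_scan_tsv(res, out / f"scan_{name}.tsv")
        cio.write_json(
            {
                "more": res.ranges_more,
                "fewer": res.ranges_fewer,
                "alpha": res.alpha,
                "theta_deg": res.theta_deg,
            },
            out / f"ranges_{name}.json",
        )
        sel = res.selection
        if sel is not None:
            cio.write_json(
                {
                    "selected": sel.selected,
                    "csr": {"lam": sel.csr.lam, "p_d": sel.csr_gof.p_d},
                    "thomas": None
                    if sel.thomas is None
                    else {
                        "kappa": sel.thomas.params.kappa,
                        "mu": sel.thomas.params.mu,
                        "sigma": sel.thomas.params.sigma,
                        "p_d": sel.thomas_gof.p_d,
                        "weak_clustering": sel.thomas.weak_clustering,
                    },
                    "tie": sel.tie,
                    "note": sel.note,
                },
                out / f"fit_{name}.json",
            )
    cio.write_run_log(out / "run_log.json", cfg.seed, config=cfg)
    return results


def poisson_histogram_pvalue(counts, E: float, min_expected: float = 5.0) -> float:
    """Chi-square p-value of observed counts against Poisson(E).

    Bins with expected frequency below ``min_expected`` are pooled into the
    tail before the test.
    """
    from scipy import stats

    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    exp = n * stats.poisson.pmf(ks, E)
    exp_tail = n * stats.poisson.sf(kmax, E)
    obs = np.bincount(counts, minlength=kmax + 1).astype(float)
    # pool from the top until the tail bin is big enough
    obs = np.append(obs, 0.0)
    exp = np.append(exp, exp_tail)
    while len(exp) > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    while len(exp) > 2 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        exp, obs = exp[1:], obs[1:]
    if len(exp) < 2:
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 1
    return float(stats.chi2.sf(stat, dof))
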
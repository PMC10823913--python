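"""Self-consistent synthetic landscapes for testing the whole workflow.

The generator emulates the statistical structure the pipeline assumes,
with no real acquisition involved:

* smooth, spatially correlated "true" stand fields (BA, Dg, BA_b) on a
  25 m cell grid, with a stratum label per cell;
* field plots located on sampled cells, whose tree lists are drawn from a
  per-stand Weibull diameter distribution and rescaled to reproduce the
  stand's (BA, Dg, BA_b) triple essentially exactly;
* lidar metrics generated as noisy stratum-specific affine functions of
  the true stand variables, so the area-based models can recover them;
* canopy height model surrogates made of isolated cones whose apexes are
  the tree heights, for the dominant-height pipeline.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import FieldPlot, StandSummary, TreeRecord
from .errors import InvalidInputError
from .heights import HeightModelParams, load_published_params, predict_height
from .metrics import HeightField

__all__ = ["SyntheticConfig", "SyntheticLandscape", "simulate_true_fields",
           "simulate_plot", "simulate_metrics", "simulate_chm",
           "simulate_landscape"]

#: species code -> (broadleaf flag, relative abundance within its class)
DEFAULT_SPECIES = {
    "Fa.sy.": (True, 0.5),
    "Qu.pe.": (True, 0.3),
    "Ac.ps.": (True, 0.2),
    "Pi.ab.": (False, 0.6),
    "Ab.al.": (False, 0.4),
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic landscape.

    Defaults describe a mid-European mixed mountain forest: mean basal
    area 25 m2/ha (sd 7), mean quadratic diameter 25 cm (sd 5), broadleaf
    share varying over the full range, ~12 trees per plot, Weibull-shaped
    diameter distributions (shape 2.3) and lidar metrics whose noise sds
    correspond to plot-level RMSEs of a few m2/ha.
    """

    nx: int = 20
    ny: int = 20
    n_strata: int = 2
    corr_range: float = 3.0  # cells; 0 = white noise
    ba_mean: float = 25.0
    ba_sd: float = 7.0
    dg_mean: float = 25.0
    dg_sd: float = 5.0
    n_plots: int = 60
    trees_per_plot: int = 12
    weibull_shape: float = 2.3
    species: dict[str, tuple[bool, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES)
    )
    # metric noise sds chosen so plot-level prediction RMSEs land in the
    # operational area-based range (BA ~5 m2/ha, Dg ~3 cm, BA_b ~0.15)
    noise_ba: float = 4.0
    noise_dg: float = 2.5
    noise_bab: float = 0.6
    n_noise_metrics: int = 2
    height_site: str = "bauges"
    height_noise_sd: float = 0.0
    seed: int = 0

    @property
    def broadleaf_map(self) -> dict[str, bool]:
        return {sp: bl for sp, (bl, _) in self.species.items()}


@dataclass
class SyntheticLandscape:
    """Bundle returned by :func:`simulate_landscape`."""

    truth: pd.DataFrame  # per-cell true BA, Dg, BA_b, stratum
    plots: list[FieldPlot]
    plot_cells: dict[str, int]  # plot_id -> cellID25 it sits on
    plot_table: pd.DataFrame  # plot metrics + observed summaries, one row per plot
    cell_metrics: pd.DataFrame  # per-cell metrics + stratum + forest flag
    config: SyntheticConfig


def _smooth_field(shape, corr_range, rng):
    z = rng.standard_normal(shape)
    if corr_range > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_range, mode="reflect")
        z = (z - z.mean()) / (z.std() or 1.0)
    return z


def simulate_true_fields(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Per-cell true (BA, Dg, BA_b) and stratum, indexed by cellID25.

    Fields are low-pass-filtered Gaussian noise rescaled to the configured
    means/sds; BA_b is squashed through a logistic so it always lies in
    [0, 1]. Cell IDs run row-major from the north-west corner. Strata are
    vertical bands (a stand-in for acquisition/composition polygons).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shape = (config.ny, config.nx)
    ba = config.ba_mean + config.ba_sd * _smooth_field(shape, config.corr_range, rng)
    dg = config.dg_mean + config.dg_sd * _smooth_field(shape, config.corr_range, rng)
    bab = 1.0 / (1.0 + np.exp(-1.5 * _smooth_field(shape, config.corr_range, rng)))
    ba = np.clip(ba, 2.0, None)
    dg = np.clip(dg, 9.0, None)
    col = np.tile(np.arange(config.nx), (config.ny, 1))
    stratum = (col * config.n_strata // max(config.nx, 1)).astype(int)
    return pd.DataFrame(
        {
            "BA": ba.ravel(),
            "Dg": dg.ravel(),
            "BA_b": bab.ravel(),
            "stratum": [f"s{k}" for k in stratum.ravel()],
        },
        index=pd.RangeIndex(config.ny * config.nx, name="cellID25"),
    )


def simulate_plot(
    target: StandSummary,
    config: SyntheticConfig,
    rng: np.random.Generator,
    plot_id: str = "p0",
    stratum: str = "all",
    with_heights: bool = False,
    height_params: HeightModelParams | None = None,
) -> FieldPlot:
    """Draw a tree list whose summary reproduces ``target`` (to ~1e-9).

    Diameters come from a Weibull(shape, scale ~ Dg) sample and are then
    rescaled so the quadratic mean is exact; species are drawn per class
    from the configured abundances; class weights are rebalanced to hit
    BA_b and diameters/weights rescaled once more so all three summary
    coordinates are attained. Raises for unattainable targets (BA <= 0).
    """
    if target.ba <= 0:
        raise InvalidInputError("cannot simulate a plot for BA <= 0")
    n = max(config.trees_per_plot, 2)
    k = config.weibull_shape
    dbh = target.dg * rng.weibull(k, size=n)
    dbh = np.clip(dbh, 0.05 * target.dg, None)

    bl_species = [s for s, (b, _) in config.species.items() if b]
    cf_species = [s for s, (b, _) in config.species.items() if not b]

    def draw_species(pool):
        wts = np.array([config.species[s][1] for s in pool])
        return rng.choice(pool, p=wts / wts.sum())

    want_bl = 0.0 < target.ba_b
    want_cf = target.ba_b < 1.0
    is_bl = np.zeros(n, dtype=bool)
    if want_bl and want_cf:
        is_bl = rng.random(n) < 0.5
        is_bl[0], is_bl[1] = True, False  # both classes must be represented
    elif want_bl:
        is_bl[:] = True
    species = [
        draw_species(bl_species if b else cf_species) for b in is_bl
    ]

    w = np.ones(n)
    ba_i = np.pi * dbh**2 / 40000.0
    # 1. rebalance class weights for BA_b
    if want_bl and want_cf:
        ba_bl = float(np.sum(w[is_bl] * ba_i[is_bl]))
        ba_cf = float(np.sum(w[~is_bl] * ba_i[~is_bl]))
        t = target.ba_b * ba_cf / ((1.0 - target.ba_b) * ba_bl)
        w[is_bl] *= t
    # 2. rescale diameters for Dg (keeps BA_b)
    dg_now = float(np.sqrt(np.sum(w * dbh**2) / np.sum(w)))
    dbh *= target.dg / dg_now
    ba_i = np.pi * dbh**2 / 40000.0
    # 3. rescale all weights for BA (keeps Dg and BA_b)
    w *= target.ba / float(np.sum(w * ba_i))

    trees = []
    for i in range(n):
        h = None
        if with_heights:
            hp = height_params or load_published_params(config.height_site)
            h = predict_height(float(dbh[i]), target.dg, species[i], hp)
            if config.height_noise_sd > 0:
                h = max(h + rng.normal(0.0, config.height_noise_sd), 1.31)
        trees.append(
            TreeRecord(
                species=species[i],
                dbh=float(dbh[i]),
                weight=float(w[i]),
                height=h,
                broadleaf=bool(is_bl[i]),
            )
        )
    return FieldPlot(plot_id=plot_id, trees=trees, stratum=stratum)


def simulate_metrics(
    truth: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-cell lidar metric surrogates: noisy affine images of the truth.

    ``m_ba``, ``m_dg``, ``m_bab`` respond to BA, Dg and BA_b with
    stratum-specific slopes/intercepts (so stratified fits genuinely pay
    off), plus ``noiseK`` columns carrying pure noise; all metrics are
    kept strictly positive so log-form models stay applicable.
    """
    strata = sorted(truth["stratum"].unique())
    coef = {
        s: {
            "ba": (5.0 + 2.0 * j, 0.8 + 0.1 * j),
            "dg": (3.0 + 1.0 * j, 0.6 + 0.05 * j),
            "bab": (2.0, 4.0 - 0.5 * j),
        }
        for j, s in enumerate(strata)
    }
    out = pd.DataFrame(index=truth.index)
    m_ba = np.empty(len(truth))
    m_dg = np.empty(len(truth))
    m_bab = np.empty(len(truth))
    for s in strata:
        m = truth["stratum"] == s
        a, b = coef[s]["ba"]
        m_ba[m] = a + b * truth.loc[m, "BA"]
        a, b = coef[s]["dg"]
        m_dg[m] = a + b * truth.loc[m, "Dg"]
        a, b = coef[s]["bab"]
        m_bab[m] = a + b * truth.loc[m, "BA_b"]
    out["m_ba"] = np.clip(m_ba + rng.normal(0, config.noise_ba, len(truth)), 0.1, None)
    out["m_dg"] = np.clip(m_dg + rng.normal(0, config.noise_dg, len(truth)), 0.1, None)
    out["m_bab"] = np.clip(
        m_bab + rng.normal(0, config.noise_bab, len(truth)), 0.1, None
    )
    for kk in range(config.n_noise_metrics):
        out[f"noise{kk}"] = np.abs(rng.normal(5.0, 1.0, len(truth))) + 0.1
    out["stratum"] = truth["stratum"].to_numpy()
    out["forest"] = True
    return out


def simulate_chm(
    heights: list[float] | np.ndarray,
    resolution: float = 1.0,
    cone_radius: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[HeightField, bool]:
    """A 25x25 m CHM of isolated cones, one per tree height.

    Apex heights equal the given tree heights; apexes are placed on a
    lattice with enough spacing that every cone apex is a strict local
    maximum. Returns ``(field, overlap_flag)``; when more trees are asked
    for than non-overlapping positions exist, overlap is allowed and the
    flag set. An empty height list yields a flat zero field.
    """
    rng = rng or np.random.default_rng(0)
    npix = int(round(25.0 / resolution))
    grid = np.zeros((npix, npix))
    hs = np.asarray(heights, dtype=float)
    if hs.size == 0:
        return HeightField(grid, resolution), False
    step = int(np.ceil(2 * cone_radius / resolution)) + 1
    margin = int(np.ceil(cone_radius / resolution))
    coords = [
        (r, c)
        for r in range(margin, npix - margin, step)
        for c in range(margin, npix - margin, step)
    ]
    overlap = len(coords) < hs.size
    if overlap:
        extra = hs.size - len(coords)
        coords = coords + [
            (int(rng.integers(1, npix - 1)), int(rng.integers(1, npix - 1)))
            for _ in range(extra)
        ]
    order = rng.permutation(len(coords))[: hs.size]
    rr, cc = np.meshgrid(np.arange(npix), np.arange(npix), indexing="ij")
    for h, idx in zip(hs, order):
        r0, c0 = coords[idx]
        dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) * resolution
        cone = np.clip(h * (1.0 - dist / cone_radius), 0.0, None)
        grid = np.maximum(grid, cone)
    return HeightField(grid, resolution), overlap


def simulate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Full self-consistent bundle: truth, plots, metrics, plot table.

    Plots sit on a random sample of distinct cells; their tree lists
    reproduce the cell truth and their metric rows are fresh noisy draws
    from the same metric model (a plot and its cell share truth, not
    noise). The returned ``plot_table`` has one row per plot with the
    observed summaries and co-located metrics, ready for model fitting.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_true_fields(config, rng)
    cell_metrics = simulate_metrics(truth, config, rng)
    n_cells = len(truth)
    if config.n_plots > n_cells:
        raise InvalidInputError("more plots than cells")
    plot_cell_ids = rng.choice(n_cells, size=config.n_plots, replace=False)
    plot_metrics = simulate_metrics(truth.iloc[plot_cell_ids], config, rng)

    plots = []
    plot_cells = {}
    rows = []
    for j, cid in enumerate(plot_cell_ids):
        t = truth.iloc[cid]
        pid = f"p{j:04d}"
        plot = simulate_plot(
            StandSummary(float(t.BA), float(t.Dg), float(t.BA_b)),
            config,
            rng,
            plot_id=pid,
            stratum=str(t.stratum),
            with_heights=True,
        )
        plots.append(plot)
        plot_cells[pid] = int(cid)
        s = plot.summary()
        row = {"plot_id": pid, "BA": s.ba, "Dg": s.dg, "BA_b": s.ba_b,
               "stratum": str(t.stratum)}
        row.update(plot_metrics.iloc[j].drop(["stratum", "forest"]).to_dict())
        rows.append(row)
    plot_table = pd.DataFrame(rows)
    return SyntheticLandscape(
        truth=truth,
        plots=plots,
        plot_cells=plot_cells,
        plot_table=plot_table,
        cell_metrics=cell_metrics,
        config=config,
    )
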
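"""Seed-reproducible synthetic datasets for the multi-scale pipeline.

The generator emulates a regional field survey of one invasive and two
native insect species: ~329 fields scattered over a 300 x 350 km
rectangle; monthly mean temperatures built from a broad east-west
gradient sampled with noise at synthetic weather stations and carried to
the fields by inverse-distance-weighted (IDW) interpolation; compositional
land-use covariates (forest, developed, crop classes) at seven buffer
scales from a shared smooth latent field with scale-specific noise; and a
distance-from-source covariate. Counts are negative binomial with a
log-linear mean; the invasive species' mean is forced to zero wherever
mean June temperature exceeds a hard thermal cutoff (23.5 degC by
default), while the natives respond positively to July temperature and
forest cover. A TruthBundle records the generating coefficients so
recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Coordinates
from .io import SiteTable
from .transform import CommunityMatrix

__all__ = [
    "SyntheticConfig",
    "TruthBundle",
    "gen_coordinates",
    "idw_interpolate",
    "gen_environment",
    "gen_abundance",
    "make_dataset",
]

MONTHS = ("mayT", "junT", "julT", "augT")
LANDUSE_CLASSES = ("forestdeci", "forestever", "forestother", "developopen", "cropscornsoy")
BUFFER_SCALES = ("100", "250", "500", "1k", "2k5", "5k", "10k")


def _default_temp_base():
    return {"mayT": 16.0, "junT": 20.5, "julT": 23.0, "augT": 22.0}


def _default_temp_slope():
    # degC gained from the west to the east edge of the extent
    return {"mayT": 4.0, "junT": 5.0, "julT": 4.0, "augT": 4.0}


def _default_scale_noise():
    # finer buffers vary more from field to field than 10-km buffers
    return {"100": 0.6, "250": 0.5, "500": 0.4, "1k": 0.3, "2k5": 0.25, "5k": 0.2, "10k": 0.15}


def _default_species():
    # log-linear coefficients on named covariates (natural units);
    # refs are the centering constants the linear predictor subtracts
    return {
        "hhalys": {
            "intercept": np.log(40.0),
            "coefficients": {"junT": -0.7, "dist_km": -0.004,
                             "developopen250": 2.5, "forestdeci250": 2.0},
            "invasive": True,
        },
        "chilaris": {
            "intercept": np.log(5.0),
            "coefficients": {"julT": 0.35, "forestdeci500": 2.0, "forestother10k": 1.5},
            "invasive": False,
        },
        "eservus": {
            "intercept": np.log(3.0),
            "coefficients": {"julT": 0.3, "forestever500": 2.0, "forestdeci500": 1.0},
            "invasive": False,
        },
    }


def _default_refs():
    return {"mayT": 18.0, "junT": 23.0, "julT": 25.0, "augT": 24.0, "dist_km": 200.0,
            "default_landuse": 0.2}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey generator."""

    n_sites: int = 329
    extent: tuple = (300.0, 350.0)          # km
    n_stations: int = 50
    idw_power: float = 2.0
    temp_base: dict = field(default_factory=_default_temp_base)
    temp_slope: dict = field(default_factory=_default_temp_slope)
    temp_noise_sd: float = 0.3              # station-level degC noise
    landuse_shared_sd: float = 0.3          # site latent shared across scales
    landuse_scale_noise: dict = field(default_factory=_default_scale_noise)
    source: tuple = None                    # defaults to the NE corner
    species: dict = field(default_factory=_default_species)
    refs: dict = field(default_factory=_default_refs)
    cutoff_junT: float = 23.5               # invasive hard thermal threshold, degC
    cutoff_mode: str = "hard"               # "hard" or "logistic"
    cutoff_steepness: float = 8.0           # per degC, logistic mode only
    dispersion: float = 1.5                 # negative binomial size; larger = less overdispersed
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        ex, ey = self.extent
        if ex <= 0 or ey <= 0:
            raise ValueError("degenerate extent")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.cutoff_mode not in ("hard", "logistic"):
            raise ValueError("cutoff_mode must be 'hard' or 'logistic'")
        jun_lo = self.temp_base["junT"]
        jun_hi = jun_lo + self.temp_slope["junT"]
        if not jun_lo - 2 < self.cutoff_junT < jun_hi + 2:
            raise ValueError("cutoff_junT lies outside the generated June temperature range")
        if self.source is None:
            self.source = (0.95 * ex, 0.95 * ey)

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, all derived from one seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stage + 1)[stage])


@dataclass(frozen=True)
class TruthBundle:
    """Generating coefficients serialized alongside every dataset."""

    species: dict
    refs: dict
    cutoff_junT: float
    cutoff_mode: str
    true_scale: str
    seed: int

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def gen_coordinates(n: int, extent: tuple, seed=None, rng=None) -> Coordinates:
    """Uniform, pairwise-distinct site coordinates over a rectangle."""
    if n < 10:
        raise ValueError("n must be >= 10")
    ex, ey = extent
    if ex <= 0 or ey <= 0:
        raise ValueError("degenerate extent")
    rng = rng if rng is not None else np.random.default_rng(seed)
    xy = np.column_stack([rng.uniform(0, ex, n), rng.uniform(0, ey, n)])
    while len(np.unique(xy, axis=0)) < n:  # essentially never with float draws
        xy = np.column_stack([rng.uniform(0, ex, n), rng.uniform(0, ey, n)])
    return Coordinates(xy=xy)


def idw_interpolate(station_xy, station_values, target_xy, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation of station values to targets.

    A target coincident with a station returns that station's value
    exactly; large powers approach nearest-neighbor assignment.
    """
    station_xy = np.atleast_2d(np.asarray(station_xy, float))
    target_xy = np.atleast_2d(np.asarray(target_xy, float))
    z = np.asarray(station_values, float)
    if station_xy.shape[0] == 0:
        raise ValueError("no stations supplied")
    if power <= 0:
        raise ValueError("power must be > 0")
    d = np.sqrt(((target_xy[:, None, :] - station_xy[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(target_xy))
    exact = d < 1e-12
    for i in range(len(target_xy)):
        hit = np.nonzero(exact[i])[0]
        if len(hit):
            out[i] = z[hit[0]]
        else:
            w = d[i] ** (-power)
            out[i] = float(w @ z / w.sum())
    return out


def gen_environment(coords: Coordinates, config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Temperatures (station gradient + IDW), land-use proportions, distance."""
    rng = rng if rng is not None else config.rng(1)
    ex, ey = config.extent
    xy = coords.xy
    env = {}

    station_xy = np.column_stack([rng.uniform(0, ex, config.n_stations),
                                  rng.uniform(0, ey, config.n_stations)])
    for month in MONTHS:
        base, slope = config.temp_base[month], config.temp_slope[month]
        station_vals = base + slope * station_xy[:, 0] / ex + rng.normal(0, config.temp_noise_sd, config.n_stations)
        env[month] = idw_interpolate(station_xy, station_vals, xy, config.idw_power)

    # one smooth latent field per land-use class, shared across buffer
    # scales; softmax over classes + an implicit "other" keeps each
    # scale's proportions in [0,1] with named classes summing to <= 1
    xr, yr = xy[:, 0] / ex, xy[:, 1] / ey
    latent = {
        "forestdeci": 0.2 - 1.2 * xr + 0.5 * np.sin(2 * np.pi * yr),
        "forestever": -0.4 - 0.6 * xr + 0.3 * np.cos(2 * np.pi * yr),
        "forestother": -0.5 + 0.4 * yr,
        "developopen": -1.0 + 1.0 * xr,
        "cropscornsoy": 0.1 + 0.7 * xr,
    }
    other = np.full(coords.n, 0.6)
    shared = {c: rng.normal(0, config.landuse_shared_sd, coords.n) for c in LANDUSE_CLASSES}
    for scale in BUFFER_SCALES:
        sd = config.landuse_scale_noise[scale]
        logits = np.column_stack(
            [latent[c] + shared[c] + rng.normal(0, sd, coords.n) for c in LANDUSE_CLASSES] + [other]
        )
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        for j, c in enumerate(LANDUSE_CLASSES):
            env[f"{c}{scale}"] = p[:, j]

    sx, sy = config.source
    env["dist_km"] = np.sqrt((xy[:, 0] - sx) ** 2 + (xy[:, 1] - sy) ** 2)
    return pd.DataFrame(env, index=pd.Index(coords.site_ids, name="site_id"))


def _linear_predictor(env: pd.DataFrame, sp_params: dict, refs: dict) -> np.ndarray:
    eta = np.full(len(env), float(sp_params["intercept"]))
    for var, beta in sp_params["coefficients"].items():
        ref = refs.get(var, refs.get("default_landuse", 0.0) if var not in MONTHS else 0.0)
        eta = eta + beta * (env[var].to_numpy() - ref)
    return eta


def gen_abundance(env: pd.DataFrame, coords: Coordinates, config: SyntheticConfig, rng=None):
    """Negative-binomial counts from log-linear means, with the invasive
    species' mean zeroed above the June-temperature cutoff."""
    rng = rng if rng is not None else config.rng(2)
    jun = env["junT"].to_numpy()
    size = config.dispersion
    mus = {}
    for name, sp_params in config.species.items():
        mu = np.exp(_linear_predictor(env, sp_params, config.refs))
        if sp_params.get("invasive"):
            if config.cutoff_mode == "hard":
                mu = np.where(jun > config.cutoff_junT, 0.0, mu)
            else:
                mu = mu / (1.0 + np.exp(config.cutoff_steepness * (jun - config.cutoff_junT)))
        mus[name] = mu

    def _draw(mu_row):
        out = np.zeros(len(mu_row), dtype=int)
        pos = mu_row > 0
        out[pos] = rng.negative_binomial(size, size / (size + mu_row[pos]))
        return out

    mu_mat = np.column_stack(list(mus.values()))
    draws = np.vstack([_draw(row) for row in mu_mat])
    # every surveyed field yields at least one individual: the joint count
    # distribution is zero-truncated per site
    for i in np.nonzero(draws.sum(axis=1) == 0)[0]:
        for _ in range(200):
            row = _draw(mu_mat[i])
            if row.sum() > 0:
                draws[i] = row
                break
        else:
            draws[i, int(np.argmax(mu_mat[i]))] = 1
    counts = {name: draws[:, j] for j, name in enumerate(mus)}
    Y = CommunityMatrix(
        counts=np.column_stack(list(counts.values())),
        species_ids=tuple(counts),
        site_ids=coords.site_ids,
    )
    truth = TruthBundle(
        species={k: {kk: vv for kk, vv in v.items()} for k, v in config.species.items()},
        refs=dict(config.refs),
        cutoff_junT=config.cutoff_junT,
        cutoff_mode=config.cutoff_mode,
        true_scale="very_broad",
        seed=config.seed,
    )
    return Y, truth


def make_dataset(config: SyntheticConfig = None, out_csv=None, out_truth=None):
    """Generate a full site table plus its truth bundle; optionally write both."""
    config = config if config is not None else SyntheticConfig()
    coords = gen_coordinates(config.n_sites, config.extent, rng=config.rng(0))
    env = gen_environment(coords, config, rng=config.rng(1))
    Y, truth = gen_abundance(env, coords, config, rng=config.rng(2))
    counts = pd.DataFrame(np.asarray(Y.counts, dtype=int), columns=list(Y.species_ids),
                          index=pd.Index(coords.site_ids, name="site_id"))
    table = SiteTable(coords=coords, env=env, counts=counts)
    if out_csv is not None:
        df = table.to_frame()
        try:
            df.to_csv(out_csv, index=False, float_format="%.10g")
        except OSError as exc:
            raise OSError(f"failed to write site table to {out_csv}: {exc}") from exc
    if out_truth is not None:
        truth.to_json(out_truth)
    return table, truth
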
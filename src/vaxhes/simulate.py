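"""Synthetic claims, geography, contact networks and panels.

The generator emulates the statistical structure a claims-derived
hesitancy panel exhibits: positive spatial autocorrelation of hesitancy
over the contact graph, a slowly rising temporal trend, dependence on
demographic composition, binomial observation noise, and heavy-tailed
child populations that leave small ZIPs sparse. The latent hesitancy field
diffuses in logit space,

    z(t) = rho * W_row z(t-1) + beta . x_demog + trend * t + noise,

with W_row the row-normalized contact graph, so rates stay inside (0, 1)
without hard clipping dominating the dynamics. Every stage is
deterministic given the config seed, and `simulate_claims` emits
person-level claim records whose quarterly ETL aggregation reproduces the
generating panel exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from scipy.special import expit, logit

from .claims import ClaimRecord
from .graphs import ContactEdge, ZipGeometry, ZipGraph
from .panel import FeatureSchema, NodePanel

__all__ = ["SimConfig", "simulate_geography", "simulate_contact_network",
           "simulate_panel", "simulate_claims", "make_linear_panel"]

_QUARTER_STARTS = {1: 1, 2: 4, 3: 7, 4: 10}


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the conditions the package's experiments assume: moderate
    positive spatial autocorrelation (rho = 0.6 keeps the generated
    hesitancy field's autocorrelation well above zero), a mild rising
    trend, spatially smooth demographic composition that drifts slowly
    quarter to quarter and drives the refusal rate, a 10% baseline rate,
    and lognormal ZIP-level child counts (median ~350 per quarter) whose
    binomial refusal draws leave each cell's observed rate noisy — the
    sparse-counts regime claims panels live in.
    """

    N: int = 100
    TS: int = 12
    seed: int = 0
    rho: float = 0.6
    trend: float = 0.05              # per-quarter drift in logit space
    beta: tuple[float, ...] = (2.5, -1.2, 1.8)
    noise_sd: float = 0.03           # extra innovation sd in logit space
    base_rate: float = 0.10
    pop_lognormal: tuple[float, float] = (5.9, 0.35)  # (mu, sigma) of exp
    share_ar: float = 0.9            # quarter-to-quarter composition AR(1)
    cluster_nodes: tuple[int, ...] = ()
    cluster_multiplier: float = 1.0
    observation_noise: bool = True   # binomial refusal counts vs exact rates
    start_year: int = 2019

    def __post_init__(self):
        if self.N < 5 or self.TS < 4:
            raise ValueError("need N >= 5 and TS >= 4")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must lie in (0, 1)")


def _zip_names(n: int) -> list[str]:
    return [f"{22000 + i:05d}" for i in range(n)]


def simulate_geography(cfg: SimConfig) -> ZipGeometry:
    """Random planar centroids with Delaunay-neighbour polygon adjacency.

    Regenerates (deterministically) until the adjacency graph is
    connected, which for Delaunay triangulations it always is.
    """
    rng = np.random.default_rng(cfg.seed)
    pts = rng.random((cfg.N, 2)) * 100.0
    tri = Delaunay(pts)
    zips = _zip_names(cfg.N)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                pairs.add(frozenset((zips[simplex[a]], zips[simplex[b]])))
    centroids = {z: (float(x), float(y)) for z, (x, y) in zip(zips, pts)}
    return ZipGeometry(adjacency_pairs=pairs, centroids=centroids)


def simulate_contact_network(geom: ZipGeometry, cfg: SimConfig
                             ) -> list[ContactEdge]:
    """Person-level contact edges whose ZIP aggregation follows a gravity law.

    Target ZIP x ZIP weights are pop_i * pop_j / dist^2 restricted to
    Delaunay neighbours plus a thinned set of longer-range pairs; each
    target weight is split across a Poisson number of person-level contacts
    via a Dirichlet draw, so aggregation recovers the target exactly.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    zips = sorted(geom.centroids)
    pts = np.array([geom.centroids[z] for z in zips])
    pops = np.exp(rng.normal(cfg.pop_lognormal[0], cfg.pop_lognormal[1],
                             size=len(zips)))
    edges: list[ContactEdge] = []
    person = 0
    for i in range(len(zips)):
        for j in range(i + 1, len(zips)):
            adjacent = frozenset((zips[i], zips[j])) in geom.adjacency_pairs
            if not adjacent and rng.random() > 0.05:
                continue                    # sparse long-range contacts
            d2 = ((pts[i] - pts[j])**2).sum()
            target = pops[i] * pops[j] / max(d2, 1.0) / 1e3
            if target <= 0:
                continue
            k = max(1, int(rng.poisson(min(target, 50.0))))
            weights = target * rng.dirichlet(np.ones(k))
            for w in weights:
                edges.append(ContactEdge(f"p{person}", f"p{person + 1}",
                                         zips[i], zips[j], float(w)))
                person += 2
    return edges


def _sar_smooth(u: np.ndarray, W_hat: np.ndarray, rho: float) -> np.ndarray:
    """Simultaneous-autoregressive smoothing (I - rho W)^-1 (1-rho) u."""
    if rho == 0:
        return u
    n = W_hat.shape[0]
    return np.linalg.solve(np.eye(n) - rho * W_hat, (1 - rho) * u)


def _demographics(rng: np.random.Generator, W_hat: np.ndarray, rho: float,
                  schema: FeatureSchema, TS: int,
                  ar: float) -> dict[str, np.ndarray]:
    """Spatially smooth, slowly drifting category shares per field.

    Latent gaussian fields per category are SAR-smoothed over the contact
    graph (neighbouring ZIPs have similar composition) and evolve as a
    stationary AR(1) in time with coefficient `ar` — the quarter-to-quarter
    drift in who files claims. Returns {field: [n, TS, n_cats]} share
    arrays.
    """
    n = W_hat.shape[0]
    shares = {}
    for fld, cats in schema.categorical_maps.items():
        c = len(cats)
        g = np.empty((n, TS, c))
        state = np.column_stack([_sar_smooth(rng.normal(size=n), W_hat, rho)
                                 for _ in range(c)])
        scale = 1.0 / max(state.std(), 1e-9)      # unit marginal scale
        state *= scale
        for t in range(TS):
            g[:, t, :] = state
            innov = np.column_stack([
                _sar_smooth(rng.normal(size=n), W_hat, rho)
                for _ in range(c)]) * scale
            state = ar * state + np.sqrt(1 - ar**2) * innov
        expo = np.exp(g)
        shares[fld] = expo / expo.sum(axis=2, keepdims=True)
    return shares


def simulate_panel(geom: ZipGeometry, g: ZipGraph, cfg: SimConfig
                   ) -> tuple[NodePanel, dict]:
    """Generate the observed panel plus the latent truth.

    Returns (panel, truth) where truth carries the latent rate field, the
    demographic shares and the per-child refusal assignments needed by
    `simulate_claims` for an exact ETL round trip.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    schema = FeatureSchema.default()
    zips = list(g.zips)
    n = len(zips)

    W = g.W.copy()
    row = W.sum(axis=1, keepdims=True)
    W_hat = np.divide(W, row, out=np.zeros_like(W), where=row > 0)

    shares = _demographics(rng, W_hat, cfg.rho, schema, cfg.TS,
                           cfg.share_ar)
    # demographic covariates entering the rate: hispanic share, medicaid
    # share, 'other/unknown race' share — the axes claims analyses flag;
    # time-varying because the claimant mix drifts quarter to quarter
    x_demog = np.stack([
        shares["hispanic"][:, :, 0],
        shares["payer_lob"][:, :, 2],
        shares["race"][:, :, 5],
    ], axis=-1)                                     # [n, TS, 3]
    beta = np.asarray(cfg.beta, dtype=np.float64)
    demog_effect = x_demog @ beta                   # [n, TS]
    # center per quarter: composition drift shapes the cross-section, the
    # panel-wide level is governed by base_rate and trend alone
    demog_effect -= demog_effect.mean(axis=0, keepdims=True)

    # latent logit field: drifting demographic level + small AR(1)
    # spatially correlated fluctuations + rising trend
    base = logit(cfg.base_rate)
    z = np.zeros((n, cfg.TS))
    s = _sar_smooth(rng.normal(0, cfg.noise_sd, size=n), W_hat, cfg.rho)
    for t in range(cfg.TS):
        s = 0.3 * s + _sar_smooth(rng.normal(0, cfg.noise_sd, size=n),
                                  W_hat, cfg.rho)
        z[:, t] = demog_effect[:, t] + s + cfg.trend * t
        if np.any(np.abs(z[:, t]) > 10):
            raise FloatingPointError(
                "latent field diverged; reduce rho, trend or beta")
    rate = expit(base + z)
    if cfg.cluster_nodes:
        idx = np.asarray(cfg.cluster_nodes)
        rate[idx] = np.clip(rate[idx] * cfg.cluster_multiplier, 0.0, 0.95)

    pops = np.exp(rng.normal(cfg.pop_lognormal[0], cfg.pop_lognormal[1],
                             size=n))
    p = np.maximum(
        rng.poisson(pops[:, None] * np.ones((1, cfg.TS))), 0).astype(np.int64)

    feature_names = schema.feature_names()
    nc = np.zeros((n, len(feature_names), cfg.TS))
    h = np.zeros((n, cfg.TS))
    child_refusals: dict[tuple[int, int], np.ndarray] = {}
    child_demogs: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    fi = {f: k for k, f in enumerate(feature_names)}
    for i in range(n):
        for t in range(cfg.TS):
            count = int(p[i, t])
            nc[i, fi["n_children"], t] = count
            if count == 0:
                continue
            if cfg.observation_noise:
                refused = rng.random(count) < rate[i, t]
            else:
                n_ref = int(round(rate[i, t] * count))
                refused = np.zeros(count, dtype=bool)
                refused[:n_ref] = True
            h[i, t] = refused.mean()
            child_refusals[(i, t)] = refused
            demogs = {}
            for fld, cats in schema.categorical_maps.items():
                cat_names = sorted(cats, key=cats.get)
                draws = rng.choice(len(cat_names), size=count,
                                   p=shares[fld][i, t])
                demogs[fld] = np.array([cat_names[d] for d in draws])
                for ci, cat in enumerate(cat_names):
                    nc[i, fi[f"{fld}={cat}"], t] = np.sum(draws == ci)
            child_demogs[(i, t)] = demogs

    timesteps = [f"{cfg.start_year + t // 4}Q{t % 4 + 1}"
                 for t in range(cfg.TS)]
    panel = NodePanel(zips, timesteps, nc, h, p, feature_names)
    truth = {"rate": rate, "z": z, "shares": shares, "schema": schema,
             "child_refusals": child_refusals, "child_demogs": child_demogs,
             "demog_effect": demog_effect}
    return panel, truth


def simulate_claims(panel: NodePanel, truth: dict, cfg: SimConfig
                    ) -> list[ClaimRecord]:
    """Emit per-child claim records reproducing the panel under the ETL.

    Each child files 1–4 claims in its quarter; refusing children get one
    Z28-coded claim among them (subcode varied), others benign codes.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    schema: FeatureSchema = truth["schema"]
    records: list[ClaimRecord] = []
    benign = ["J06.9", "Z00.129", "R05", "H66.90"]
    z28 = ["Z28.0", "Z28.21", "Z28.82", "Z28.9"]
    for (i, t), refused in truth["child_refusals"].items():
        zip_id = panel.zips[i]
        qlabel = panel.timesteps[t]
        year, q = int(qlabel[:4]), int(qlabel[-1])
        month0 = _QUARTER_STARTS[q]
        demogs = truth["child_demogs"][(i, t)]
        for child in range(refused.size):
            key = f"{zip_id}-{qlabel}-c{child}"
            n_claims = int(rng.integers(1, 5))
            refusal_at = int(rng.integers(n_claims)) if refused[child] else -1
            for ci in range(n_claims):
                date = _dt.date(year, month0 + int(rng.integers(3)),
                                int(rng.integers(1, 29)))
                code = (str(rng.choice(z28)) if ci == refusal_at
                        else str(rng.choice(benign)))
                records.append(ClaimRecord(
                    person_key=key, incurred_date=date, zip=zip_id,
                    age_years=int(rng.integers(0, 7)),
                    gender=str(demogs["gender"][child]),
                    race=str(demogs["race"][child]),
                    hispanic=str(demogs["hispanic"][child]),
                    payer_lob=str(demogs["payer_lob"][child]),
                    dx_code=code))
    return records


def make_linear_panel(N: int = 30, TS: int = 8, seed: int = 0,
                      n_features: int = 4) -> NodePanel:
    """Noiseless panel with h(t) an exact linear function of nc(t).

    An identifiable instance for recovery tests: the spatial module can
    drive its training error toward zero because the target is a fixed
    linear map of the (already normalized) features.
    """
    rng = np.random.default_rng(seed)
    nc = rng.random((N, n_features, TS))
    w = rng.random(n_features)
    w /= w.sum() * 2.0               # keep h within (0, 0.5)
    b = 0.1
    h = np.clip(np.einsum("nxt,x->nt", nc, w) + b, 0.0, 1.0)
    p = np.full((N, TS), 1000, dtype=np.int64)
    zips = _zip_names(N)
    timesteps = [f"{2020 + t // 4}Q{t % 4 + 1}" for t in range(TS)]
    names = [f"x{k}" for k in range(n_features)]
    return NodePanel(zips, timesteps, nc, h, p, names, normalized=True)
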
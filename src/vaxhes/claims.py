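"""Claims-record ETL: from raw claims-like rows to the quarterly node panel.

The pipeline mirrors how childhood vaccine hesitancy is derived from
insurance claims: keep claims of children aged six or below, flag refusal
via the ICD-10-CM Z28 family ("Immunization not carried out and
underimmunization status"), aggregate to ZIP x calendar-quarter cells,
one-hot-count demographic categories, and per-timestep min-max normalize
the feature columns. Hesitancy h_i(t) is the fraction of *unique* children
in the cell with at least one refusal-flagged claim.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .panel import FeatureSchema, NodePanel

__all__ = [
    "ClaimRecord",
    "read_claims_csv",
    "filter_child_claims",
    "flag_refusal",
    "aggregate_quarterly",
    "filter_zip_population",
    "normalize_features",
    "pca_transform",
]


@dataclass(frozen=True)
class ClaimRecord:
    person_key: str
    incurred_date: _dt.date
    zip: str
    age_years: int
    gender: str = "unknown"
    race: str = "unknown"
    hispanic: str = "unknown"
    payer_lob: str = "commercial"
    refusal: bool | None = None
    dx_code: str | None = None

    def __post_init__(self):
        if not self.zip:
            raise ValueError("empty ZIP on claim record")
        if self.age_years < 0:
            raise ValueError("negative age on claim record")


def read_claims_csv(path: str | Path,
                    column_map: dict[str, str] | None = None) -> list[ClaimRecord]:
    """Read claim records from a delimited file with a header row.

    `column_map` renames file columns to the canonical field names; fields
    absent from the file fall back to ClaimRecord defaults.
    """
    df = pd.read_csv(path, dtype={"zip": str, "person_key": str})
    if column_map:
        df = df.rename(columns=column_map)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        refusal = d.get("refusal")
        records.append(ClaimRecord(
            person_key=str(d["person_key"]),
            incurred_date=pd.Timestamp(d["incurred_date"]).date(),
            zip=str(d["zip"]),
            age_years=int(d["age_years"]),
            gender=str(d.get("gender", "unknown")),
            race=str(d.get("race", "unknown")),
            hispanic=str(d.get("hispanic", "unknown")),
            payer_lob=str(d.get("payer_lob", "commercial")),
            refusal=None if refusal is None or pd.isna(refusal) else bool(refusal),
            dx_code=None if pd.isna(d.get("dx_code")) else str(d["dx_code"]),
        ))
    return records


def filter_child_claims(records: Iterable[ClaimRecord],
                        max_age: int = 6) -> list[ClaimRecord]:
    """Keep claims of children aged `max_age` or below (age at service)."""
    if max_age < 0:
        raise ValueError("max_age must be nonnegative")
    return [r for r in records if r.age_years <= max_age]


def flag_refusal(record: ClaimRecord) -> bool:
    """True iff the claim indicates vaccine refusal.

    A claim counts as refusal when its diagnosis code is in the ICD-10-CM
    Z28 category (any subcode, e.g. Z28.21), or its explicit refusal flag
    is set.
    """
    if record.refusal is None and record.dx_code is None:
        raise ValueError("claim has neither a refusal flag nor a dx code")
    if record.refusal:
        return True
    if record.dx_code is not None:
        return record.dx_code.strip().upper().startswith("Z28")
    return False


def _quarter_label(date: _dt.date) -> str:
    return f"{date.year}Q{(date.month - 1) // 3 + 1}"


def aggregate_quarterly(records: Sequence[ClaimRecord],
                        schema: FeatureSchema | None = None,
                        zips_keep: set[str] | None = None,
                        timesteps: list[str] | None = None) -> NodePanel:
    """Aggregate child claims into the quarterly ZIP-level panel.

    Per cell (i, t): p_i(t) = number of unique children with >= 1 claim,
    feature columns = unique-child counts per one-hot category plus the
    total, h_i(t) = unique children with >= 1 refusal-flagged claim divided
    by p_i(t). Cells with p = 0 get h = 0 and are masked out.
    """
    schema = schema or FeatureSchema.default()
    if zips_keep is not None and not zips_keep:
        raise ValueError("zips_keep must be nonempty when given")
    records = [r for r in records
               if zips_keep is None or r.zip in zips_keep]
    if not records:
        raise ValueError("no claim records in any kept ZIP")

    zips = sorted({r.zip for r in records} if zips_keep is None else zips_keep)
    if timesteps is None:
        timesteps = sorted({_quarter_label(r.incurred_date) for r in records})
    feature_names = schema.feature_names()
    zi = {z: i for i, z in enumerate(zips)}
    ti = {t: j for j, t in enumerate(timesteps)}
    fi = {f: k for k, f in enumerate(feature_names)}

    # per cell: person -> (refused?, demographics); unique-child semantics
    cell_children: dict[tuple[int, int], dict[str, dict]] = {}
    for r in records:
        q = _quarter_label(r.incurred_date)
        if q not in ti:
            continue
        key = (zi[r.zip], ti[q])
        child = cell_children.setdefault(key, {}).setdefault(
            r.person_key, {"refused": False, "demog": r})
        if flag_refusal(r):
            child["refused"] = True

    N, TS, X = len(zips), len(timesteps), len(feature_names)
    nc = np.zeros((N, X, TS))
    h = np.zeros((N, TS))
    p = np.zeros((N, TS), dtype=np.int64)
    for (i, t), children in cell_children.items():
        p[i, t] = len(children)
        n_refused = sum(c["refused"] for c in children.values())
        h[i, t] = n_refused / len(children)
        nc[i, fi["n_children"], t] = len(children)
        for c in children.values():
            r = c["demog"]
            for fld, cats in schema.categorical_maps.items():
                val = getattr(r, fld)
                col = f"{fld}={val if val in cats else 'unknown'}"
                nc[i, fi[col], t] += 1
    return NodePanel(zips, list(timesteps), nc, h, p, feature_names)


def filter_zip_population(panel: NodePanel, populations: dict[str, int],
                          min_pop: int = 1000) -> NodePanel:
    """Retain ZIPs with total population strictly above `min_pop`.

    Graph consumers must subset their weight matrices to the same ZIP set.
    """
    missing = [z for z in panel.zips if z not in populations]
    if missing:
        raise ValueError(f"missing population for ZIPs: {missing[:5]}")
    keep = [z for z in panel.zips if populations[z] > min_pop]
    return panel.subset_zips(keep)


def normalize_features(panel: NodePanel, normalize_h: bool = False) -> NodePanel:
    """Min-max normalize every feature column within each timestep.

    Columns constant across nodes at a timestep map to 0. By default h is
    left as a raw fraction (already in [0, 1]); `normalize_h=True` applies
    the same per-timestep min-max to h as well.
    """
    nc = panel.nc.copy()
    lo = nc.min(axis=0)                      # [X, TS]
    hi = nc.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    nc = (nc - lo[None]) / safe[None]
    nc[:, span == 0] = 0.0
    h = panel.h.copy()
    constants = {"feature_min": lo, "feature_span": span}
    if normalize_h:
        hlo, hhi = h.min(axis=0), h.max(axis=0)
        hspan = np.where(hhi - hlo > 0, hhi - hlo, 1.0)
        h = (h - hlo[None]) / hspan[None]
        h[:, (hhi - hlo) == 0] = 0.0
        constants.update({"h_min": hlo, "h_span": hspan})
    return NodePanel(list(panel.zips), list(panel.timesteps), nc, h,
                     panel.p.copy(), list(panel.feature_names),
                     mask=panel.mask.copy(), normalized=True,
                     norm_constants=constants)


def pca_transform(panel: NodePanel, n_components: int) -> NodePanel:
    """Replace features by their first `n_components` principal scores.

    The PCA basis is fitted once, pooled over all node-timestep rows.
    Off by default in the pipeline; explained-variance ratios are stored in
    `norm_constants["pca_explained_variance_ratio"]`.
    """
    X = panel.n_features
    if n_components > X:
        raise ValueError(f"n_components {n_components} > n_features {X}")
    flat = panel.nc.transpose(0, 2, 1).reshape(-1, X)    # [N*TS, X]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(flat)
    nc = scores.reshape(panel.n_nodes, panel.n_timesteps, n_components) \
        .transpose(0, 2, 1)
    constants = dict(panel.norm_constants)
    constants["pca_explained_variance_ratio"] = pca.explained_variance_ratio_
    return NodePanel(list(panel.zips), list(panel.timesteps), nc, panel.h.copy(),
                     panel.p.copy(), [f"pc{k + 1}" for k in range(n_components)],
                     mask=panel.mask.copy(), normalized=panel.normalized,
                     norm_constants=constants)
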
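"""The per-ZIP, per-quarter feature/target panel consumed by every learner.

A :class:`NodePanel` holds the feature tensor ``nc`` with shape
``[N, X, TS]``, the hesitancy matrix ``h`` with shape ``[N, TS]`` (fraction
of unique children with at least one vaccine-refusal claim), the unique-
child count matrix ``p``, and a mask marking ZIP-quarter cells with no
observed children. The ZIP ordering is shared with the graph modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NodePanel", "FeatureSchema"]


@dataclass
class FeatureSchema:
    """One-hot layout of the categorical claim features.

    `categorical_maps` maps field name -> {category: column offset within
    that field's block}; unknown/missing categories get their own column.
    """

    categorical_maps: dict[str, dict[str, int]]
    include_pca: bool = False
    n_components: int = 0

    @classmethod
    def default(cls) -> "FeatureSchema":
        return cls(categorical_maps={
            "gender": {"male": 0, "female": 1, "unknown": 2},
            "race": {"american_indian": 0, "asian": 1, "black": 2,
                     "pacific_islander": 3, "white": 4, "other": 5,
                     "unknown": 6},
            "hispanic": {"yes": 0, "no": 1, "unknown": 2},
            "payer_lob": {"commercial": 0, "medicare": 1, "medicaid": 2},
        })

    def feature_names(self) -> list[str]:
        names = ["n_children"]
        for fld, cats in self.categorical_maps.items():
            for cat in sorted(cats, key=cats.get):
                names.append(f"{fld}={cat}")
        return names


@dataclass
class NodePanel:
    zips: list[str]
    timesteps: list[str]
    nc: np.ndarray                     # [N, X, TS]
    h: np.ndarray                      # [N, TS], fractions in [0, 1]
    p: np.ndarray                      # [N, TS], unique-children counts
    feature_names: list[str]
    mask: np.ndarray = None            # [N, TS] True where observed (p > 0)
    normalized: bool = False
    norm_constants: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nc = np.asarray(self.nc, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        self.p = np.asarray(self.p)
        n, ts = len(self.zips), len(self.timesteps)
        if len(set(self.zips)) != n:
            raise ValueError("duplicate ZIPs in panel")
        if self.nc.shape != (n, len(self.feature_names), ts):
            raise ValueError(
                f"nc shape {self.nc.shape} != ({n}, {len(self.feature_names)}, {ts})")
        if self.h.shape != (n, ts) or self.p.shape != (n, ts):
            raise ValueError("h/p shape mismatch")
        if np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("h must lie in [0, 1]")
        if np.any(self.p < 0):
            raise ValueError("p must be nonnegative")
        if self.mask is None:
            self.mask = self.p > 0
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.zips)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_timesteps(self) -> int:
        return len(self.timesteps)

    def subset_zips(self, keep: list[str]) -> "NodePanel":
        idx = [self.zips.index(z) for z in keep]
        return NodePanel(list(keep), list(self.timesteps), self.nc[idx],
                         self.h[idx], self.p[idx], list(self.feature_names),
                         mask=self.mask[idx], normalized=self.normalized,
                         norm_constants=dict(self.norm_constants))

    # ---- serialization: directory of CSVs + JSON sidecar ---------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, z in enumerate(self.zips):
            for k, f in enumerate(self.feature_names):
                for t, q in enumerate(self.timesteps):
                    rows.append((z, q, f, self.nc[i, k, t]))
        pd.DataFrame(rows, columns=["zip", "quarter", "feature", "value"]) \
            .to_csv(outdir / "features.csv", index=False)
        pd.DataFrame(self.h, index=self.zips, columns=self.timesteps) \
            .to_csv(outdir / "hesitancy.csv", index_label="zip")
        pd.DataFrame(self.p, index=self.zips, columns=self.timesteps) \
            .to_csv(outdir / "population.csv", index_label="zip")
        sidecar = {
            "zips": self.zips, "timesteps": self.timesteps,
            "feature_names": self.feature_names,
            "normalized": self.normalized,
            "norm_constants": {k: np.asarray(v).tolist()
                               for k, v in self.norm_constants.items()},
            "mask": self.mask.astype(int).tolist(),
        }
        (outdir / "panel.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, outdir: str | Path) -> "NodePanel":
        outdir = Path(outdir)
        sidecar = json.loads((outdir / "panel.json").read_text())
        zips = [str(z) for z in sidecar["zips"]]
        timesteps = [str(t) for t in sidecar["timesteps"]]
        feature_names = sidecar["feature_names"]
        zi = {z: i for i, z in enumerate(zips)}
        ti = {t: j for j, t in enumerate(timesteps)}
        fi = {f: k for k, f in enumerate(feature_names)}
        nc = np.zeros((len(zips), len(feature_names), len(timesteps)))
        feats = pd.read_csv(outdir / "features.csv", dtype={"zip": str, "quarter": str})
        for z, q, f, v in feats.itertuples(index=False):
            nc[zi[z], fi[f], ti[q]] = v
        h = pd.read_csv(outdir / "hesitancy.csv", index_col="zip") \
            .to_numpy(dtype=np.float64)
        p = pd.read_csv(outdir / "population.csv", index_col="zip").to_numpy()
        return cls(zips, timesteps, nc, h, p, feature_names,
                   mask=np.array(sidecar["mask"], dtype=bool),
                   normalized=sidecar["normalized"],
                   norm_constants={k: np.array(v) for k, v in
                                   sidecar["norm_constants"].items()})
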
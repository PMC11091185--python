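"""Posterior draw container with chain structure, CSV round-trip and arviz export."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws"]


@dataclass
class PosteriorDraws:
    """Sampled parameter arrays indexed chain x iteration.

    ``params`` maps a parameter name to an array of shape
    (chains, iterations) for scalars or (chains, iterations, *dims) for
    vectors/matrices.  ``meta`` records sampler settings (chains, warmup,
    seed, variant, ...); ``diagnostics`` holds R-hat / ESS tables computed
    after sampling.
    """

    params: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {k: v.shape[:2] for k, v in self.params.items()}
        first = next(iter(shapes.values()))
        if first[0] < 2:
            raise ValueError("PosteriorDraws requires >= 2 chains")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"inconsistent chain/iteration shapes: {shapes}")
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws in parameter {k!r}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` pooled across chains: (chains*iters, *dims)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def scalar_names(self) -> list[str]:
        """Flat names for every scalar component, e.g. ``tau[0,1]``."""
        names = []
        for k, v in self.params.items():
            if v.ndim == 2:
                names.append(k)
            else:
                for idx in np.ndindex(v.shape[2:]):
                    names.append(f"{k}[{','.join(map(str, idx))}]")
        return names

    def scalar(self, flat_name: str) -> np.ndarray:
        """(chains, iters) array for a flat scalar name."""
        m = re.fullmatch(r"([^\[\]]+)(?:\[([\d,]+)\])?", flat_name)
        if m is None:
            raise KeyError(flat_name)
        base, idx = m.group(1), m.group(2)
        v = self.params[base]
        if idx is None:
            if v.ndim != 2:
                raise KeyError(f"{flat_name}: parameter {base!r} is not scalar")
            return v
        sel = tuple(int(i) for i in idx.split(","))
        return v[(slice(None), slice(None)) + sel]

    # --- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long/wide frame: one row per (chain, draw), one column per scalar."""
        C, T = self.n_chains, self.n_draws
        cols = {
            "chain": np.repeat(np.arange(C), T),
            "draw": np.tile(np.arange(T), C),
        }
        for name in self.scalar_names():
            cols[name] = self.scalar(name).reshape(-1)
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(
            json.dumps({"meta": self.meta, "diagnostics": self.diagnostics}, indent=1)
        )

    @classmethod
    def load_csv(cls, path: str | Path) -> "PosteriorDraws":
        path = Path(path)
        df = pd.read_csv(path)
        C = int(df["chain"].max()) + 1
        T = int(df["draw"].max()) + 1
        grouped: dict[str, dict[tuple, np.ndarray]] = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            m = re.fullmatch(r"([^\[\]]+)(?:\[([\d,]+)\])?", col)
            base = m.group(1)
            idx = tuple(int(i) for i in m.group(2).split(",")) if m.group(2) else ()
            grouped.setdefault(base, {})[idx] = df[col].to_numpy().reshape(C, T)
        params = {}
        for base, comps in grouped.items():
            if list(comps) == [()]:
                params[base] = comps[()]
            else:
                dims = tuple(max(i[d] for i in comps) + 1 for d in range(len(next(iter(comps)))))
                arr = np.empty((C, T) + dims)
                for idx, vals in comps.items():
                    arr[(slice(None), slice(None)) + idx] = vals
                params[base] = arr
        meta: dict = {}
        diagnostics: dict = {}
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            blob = json.loads(sidecar.read_text())
            meta = blob.get("meta", {})
            diagnostics = blob.get("diagnostics", {})
        return cls(params=params, meta=meta, diagnostics=diagnostics)

    def to_inference_data(self):
        """arviz InferenceData view (for ESS, plotting, further diagnostics)."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.params.items()})
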
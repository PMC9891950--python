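"""Deficit-accumulation frailty index (FI).

The FI follows the Rockwood accumulation-of-deficits model: a fixed list of
health-deficit items, each mapped to a score in [0, 1] (0 = deficit absent,
1 = maximal expression), averaged over the items considered.  The default
registry holds 29 items across functional limitations, self-reported
health, CES-D-8 depressive symptoms, medical conditions and cognitive
status; a revised 26-item variant excludes the hypertension, stroke and
diabetes items so the index is free of overlap with cardiovascular risk
inputs.  Frailty status is FI >= 0.25 (inclusive).

Completeness policy: by default a participant-wave needs >= 80% of subset
items non-missing and the FI divides by the number of non-missing items;
``strict=True`` requires every item and divides by the full subset size.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DataError

__all__ = [
    "DeficitItem",
    "DeficitRegistry",
    "map_item",
    "compute_fi",
    "classify_frail",
    "compute_fi_panel",
    "FRAILTY_THRESHOLD",
]

FRAILTY_THRESHOLD = 0.25

_MISSING = float("nan")


@dataclass(frozen=True)
class DeficitItem:
    name: str
    kind: str  # binary | ordinal | scale
    domain: str
    levels: Mapping[float, float] | None = None
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "scale"):
            raise ConfigurationError(f"unknown item kind {self.kind!r} for {self.name}")
        if self.kind == "ordinal":
            if not self.levels:
                raise ConfigurationError(f"ordinal item {self.name} needs a levels map")
            vals = list(self.levels.values())
            if min(vals) != 0.0 or max(vals) != 1.0:
                raise ConfigurationError(
                    f"item {self.name}: mapping must attain 0 and 1"
                )


class DeficitRegistry:
    """Ordered item definitions plus the 29-/26-item subsets."""

    def __init__(self, items: Iterable[DeficitItem]):
        self.items = list(items)
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate item names in registry")
        self._by_name = {it.name: it for it in self.items}

    @classmethod
    def default(cls) -> "DeficitRegistry":
        path = resources.files("frailtraj") / "data" / "deficit_registry.yaml"
        with path.open("r") as fh:
            return cls.from_config(yaml.safe_load(fh))

    @classmethod
    def from_file(cls, path) -> "DeficitRegistry":
        with open(path, "r") as fh:
            return cls.from_config(yaml.safe_load(fh))

    @classmethod
    def from_config(cls, config: Mapping) -> "DeficitRegistry":
        items = []
        for entry in config["items"]:
            levels = entry.get("levels")
            if levels is not None:
                levels = {float(k): float(v) for k, v in levels.items()}
            items.append(
                DeficitItem(
                    name=entry["name"],
                    kind=entry["kind"],
                    domain=entry.get("domain", ""),
                    levels=levels,
                    tags=tuple(entry.get("tags", ())),
                )
            )
        return cls(items)

    def to_config(self) -> dict:
        out = []
        for it in self.items:
            entry = {"name": it.name, "kind": it.kind, "domain": it.domain}
            if it.levels is not None:
                entry["levels"] = {k: v for k, v in it.levels.items()}
            if it.tags:
                entry["tags"] = list(it.tags)
            out.append(entry)
        return {"items": out}

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, name: str) -> DeficitItem:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"item {name!r} not in registry") from None

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def subset(self, which: str = "full") -> list[str]:
        """Item names for the full (29) or revised (26) index.

        The revised subset drops every item tagged hypertension, stroke or
        diabetes.
        """
        if which in ("full", "29"):
            return self.names
        if which in ("revised", "26"):
            drop = {"hypertension", "stroke", "diabetes"}
            return [it.name for it in self.items if not (set(it.tags) & drop)]
        raise ConfigurationError(f"unknown subset {which!r}")


def map_item(raw, item: DeficitItem, context: str = "") -> float:
    """Map a raw recorded value to a deficit score in [0, 1].

    Missing raw values map to missing scores — never imputed to zero.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return _MISSING
    where = f" ({context})" if context else ""
    if item.kind == "binary":
        v = float(raw)
        if v not in (0.0, 1.0):
            raise DataError(f"item {item.name}{where}: binary raw value {raw!r} not in {{0,1}}")
        return v
    if item.kind == "ordinal":
        v = float(raw)
        if v not in item.levels:
            raise DataError(
                f"item {item.name}{where}: raw level {raw!r} not in declared levels "
                f"{sorted(item.levels)}"
            )
        return item.levels[v]
    # scale: already on [0,1]
    v = float(raw)
    if not 0.0 <= v <= 1.0:
        raise DataError(f"item {item.name}{where}: scale value {raw!r} outside [0,1]")
    return v


def classify_frail(fi: float) -> bool:
    """Frailty status: FI >= 0.25, boundary inclusive."""
    if np.isnan(fi):
        raise DataError("cannot classify a missing FI")
    if not 0.0 <= fi <= 1.0:
        raise DataError(f"FI {fi} outside [0,1]")
    return bool(fi >= FRAILTY_THRESHOLD)


def compute_fi(
    scores: Mapping[str, float],
    registry: DeficitRegistry,
    item_subset: str | Iterable[str] = "full",
    min_complete: float = 0.8,
    strict: bool = False,
) -> dict:
    """One FI panel row from mapped deficit scores.

    ``scores`` maps item name -> deficit score in [0,1] (NaN = missing).
    Returns dict with fi, frail, n_items_used, complete.  When the
    completeness policy fails, fi/frail are missing and ``complete`` False.
    """
    names = registry.subset(item_subset) if isinstance(item_subset, str) else list(item_subset)
    if len(names) not in (26, 29):
        raise ConfigurationError(
            f"item subset must have 29 (full) or 26 (revised) items, got {len(names)}"
        )
    vals = np.array([scores.get(n, _MISSING) for n in names], dtype=float)
    bad = vals[~np.isnan(vals)]
    if bad.size and ((bad < 0).any() or (bad > 1).any()):
        raise DataError("deficit scores must lie in [0,1]")
    n_obs = int((~np.isnan(vals)).sum())
    if strict:
        ok = n_obs == len(names)
        denom = len(names)
    else:
        ok = n_obs >= min_complete * len(names)
        denom = n_obs
    if not ok or n_obs == 0:
        return {"fi": _MISSING, "frail": None, "n_items_used": n_obs, "complete": False}
    fi = float(np.nansum(vals) / denom)
    return {"fi": fi, "frail": classify_frail(fi), "n_items_used": n_obs, "complete": True}


def compute_fi_panel(
    cohort: pd.DataFrame,
    registry: DeficitRegistry | None = None,
    item_subset: str = "full",
    min_complete: float = 0.8,
    strict: bool = False,
    mapped: bool = False,
) -> pd.DataFrame:
    """FI panel (participant_id, wave_index, years, fi, frail, n_items_used)
    from a long-format cohort table whose deficit-item columns carry raw
    values (or already-mapped scores when ``mapped=True``).
    """
    registry = registry or DeficitRegistry.default()
    names = registry.subset(item_subset)
    present = [n for n in names if n in cohort.columns]
    if len(present) != len(names):
        missing_cols = sorted(set(names) - set(present))
        raise ConfigurationError(f"cohort table lacks deficit columns: {missing_cols}")

    # vectorised mapping per column
    score_mat = np.empty((len(cohort), len(names)))
    for j, n in enumerate(names):
        col = cohort[n].to_numpy(dtype=float)
        item = registry[n]
        if mapped or item.kind == "scale":
            out = col.copy()
            obs = ~np.isnan(out)
            if ((out[obs] < 0) | (out[obs] > 1)).any():
                raise DataError(f"item {n}: mapped scores outside [0,1]")
        elif item.kind == "binary":
            out = col.copy()
            obs = ~np.isnan(out)
            if (~np.isin(out[obs], (0.0, 1.0))).any():
                raise DataError(f"item {n}: binary raw values outside {{0,1}}")
        else:  # ordinal
            out = np.full_like(col, np.nan)
            obs = ~np.isnan(col)
            lv = item.levels
            ok = np.isin(col[obs], list(lv))
            if not ok.all():
                raise DataError(f"item {n}: raw level outside declared levels")
            out[obs] = np.array([lv[v] for v in col[obs]])
        score_mat[:, j] = out

    n_obs = (~np.isnan(score_mat)).sum(axis=1)
    total = np.nansum(score_mat, axis=1)
    if strict:
        complete = n_obs == len(names)
        denom = np.full(len(cohort), float(len(names)))
    else:
        complete = n_obs >= min_complete * len(names)
        denom = n_obs.astype(float)
    fi = np.where(complete & (n_obs > 0), total / np.where(denom > 0, denom, 1.0), np.nan)

    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "wave_index": cohort["wave_index"].to_numpy(),
            "years_since_baseline": cohort["years_since_baseline"].to_numpy(),
            "fi": fi,
            "frail": pd.array(
                np.where(np.isnan(fi), None, fi >= FRAILTY_THRESHOLD), dtype="boolean"
            ),
            "n_items_used": n_obs,
        }
    )
    return out
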
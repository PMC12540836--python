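"""MSA dose-response relationships for the direct drivers of intactness loss.

Each relationship is a logistic curve mapping a single environmental
covariate to a mean species abundance (MSA) value in (0, 1):

    MSA = 1 / (1 + exp(c0 + c1 * f(x)))

where ``f`` is either the identity or a logarithm (base 10 by default,
configurable to natural log).  Habitat-loss relationships are constant
(``c1 = 0``): each human land-use class carries a fixed residual MSA.
Mines are a special case with MSA fixed at exactly 0 (complete loss of
biodiversity at the extraction site).

The default relationship set covers two species groups:

* vascular plants — climate change, nitrogen deposition, habitat loss;
* warm-blooded vertebrates (birds & mammals) — climate change, habitat
  loss, habitat fragmentation (patch size) and habitat disturbance
  (distance to the nearest road or mine, within a 5 km impact zone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Driver",
    "ResponseCurve",
    "RelationshipSet",
    "load_default_relationships",
    "DISTURBANCE_CUTOFF_M",
]

#: Disturbance by roads and mines is confined to an impact zone of 5 km.
DISTURBANCE_CUTOFF_M = 5000.0


class Group(str, Enum):
    """Species group a relationship applies to."""

    PLANTS = "plants"
    VERTEBRATES = "vertebrates"


class Driver(str, Enum):
    """Direct driver of MSA loss."""

    CLIMATE = "climate"
    NITROGEN = "nitrogen"
    HABITAT_LOSS = "habitat_loss"
    FRAGMENTATION = "fragmentation"
    DISTURBANCE = "disturbance"


@dataclass(frozen=True)
class ResponseCurve:
    """One MSA impact relationship.

    Parameters
    ----------
    group, driver
        Species group and direct driver the curve applies to.
    landuse_class
        Land-use class name for habitat-loss curves, ``None`` otherwise.
    c0, c1
        Intercept and slope of the linear predictor.  ``c1 = 0`` makes
        the curve constant (the covariate is ignored).
    transform
        ``"identity"``, ``"log"`` or ``"none"`` (constant curve).
    fixed_msa
        If set, the curve returns this value exactly and ignores the
        linear predictor (used for the mine rule, MSA = 0).
    covariate_units
        Units of the covariate, for documentation and table output.
    """

    group: Group
    driver: Driver
    landuse_class: str | None = None
    c0: float = 0.0
    c1: float = 0.0
    transform: str = "identity"
    fixed_msa: float | None = None
    covariate_units: str = "none"

    def evaluate(self, covariate: float | np.ndarray, log_base: float = 10.0):
        """Evaluate the curve at one or more covariate values.

        Constant curves (``c1 = 0`` or ``transform = 'none'``) ignore the
        covariate.  ``log`` curves require a strictly positive covariate;
        callers are expected to apply the relevant floor (minimum
        distance, minimum patch size) beforehand.
        """
        if self.fixed_msa is not None:
            if np.ndim(covariate) == 0:
                return float(self.fixed_msa)
            return np.full(np.shape(covariate), self.fixed_msa, dtype=float)
        x = np.asarray(covariate, dtype=float)
        if self.transform == "log" and self.c1 != 0.0:
            if np.any(x <= 0.0):
                raise ValueError(
                    f"log-transformed covariate must be > 0 for {self.driver.value} "
                    f"curve; apply the distance/patch-size floor first"
                )
            fx = np.log(x) / math.log(log_base)
        elif self.transform in ("identity", "log"):
            if np.any(x < 0.0):
                raise ValueError("covariate must be non-negative")
            fx = x
        elif self.transform == "none":
            fx = 0.0
        else:
            raise ValueError(f"unknown transform {self.transform!r}")
        eta = self.c0 + self.c1 * fx
        msa = 1.0 / (1.0 + np.exp(eta))
        if np.ndim(covariate) == 0:
            return float(msa)
        return msa


class RelationshipSet:
    """A keyed collection of response curves plus evaluation configuration.

    Curves are keyed by ``(group, driver)`` for covariate-driven curves
    and ``(group, driver, landuse_class)`` for habitat loss.
    """

    def __init__(self, curves: Iterable[ResponseCurve], log_base: float = 10.0):
        self.log_base = float(log_base)
        self._curves: dict[tuple, ResponseCurve] = {}
        for c in curves:
            self._curves[self._key(c.group, c.driver, c.landuse_class)] = c

    @staticmethod
    def _key(group: Group, driver: Driver, landuse_class: str | None):
        return (Group(group), Driver(driver), landuse_class)

    def get(self, group: Group, driver: Driver, landuse_class: str | None = None) -> ResponseCurve:
        key = self._key(group, driver, landuse_class)
        if key not in self._curves:
            raise KeyError(
                f"no response curve for group={Group(group).value}, "
                f"driver={Driver(driver).value}, class={landuse_class}"
            )
        return self._curves[key]

    def has(self, group: Group, driver: Driver, landuse_class: str | None = None) -> bool:
        return self._key(group, driver, landuse_class) in self._curves

    def __iter__(self):
        return iter(self._curves.values())

    def __len__(self):
        return len(self._curves)

    # -- evaluation helpers -------------------------------------------------

    def msa_climate(self, group: Group, gmti: float) -> float:
        """MSA due to climate change at a global mean temperature increase (degC)."""
        return self.get(group, Driver.CLIMATE).evaluate(gmti, self.log_base)

    def msa_nitrogen(self, group: Group, deposition):
        """MSA due to nitrogen deposition (kg N ha-1 yr-1).

        Zero deposition means no impact (MSA = 1); the log curve is only
        evaluated where deposition is positive.
        """
        curve = self.get(group, Driver.NITROGEN)
        dep = np.asarray(deposition, dtype=float)
        out = np.ones_like(dep)
        pos = dep > 0.0
        if np.any(pos):
            out[pos] = curve.evaluate(dep[pos], self.log_base)
        if np.ndim(deposition) == 0:
            return float(out)
        return out

    def msa_habitat_loss(self, group: Group, landuse_class: str) -> float:
        """Residual MSA under a given human land-use class (mines give 0)."""
        return self.get(group, Driver.HABITAT_LOSS, landuse_class).evaluate(0.0)

    def msa_fragmentation(self, group: Group, patch_size_ha):
        """MSA due to habitat fragmentation as a function of patch size (ha).

        Strictly increasing in patch size: larger patches retain more of
        the original community.
        """
        ps = np.asarray(patch_size_ha, dtype=float)
        if np.any(ps <= 0.0):
            raise ValueError("patch size must be positive (ha)")
        return self.get(group, Driver.FRAGMENTATION).evaluate(patch_size_ha, self.log_base)

    def msa_disturbance(self, group: Group, distance_m, cutoff_m: float = DISTURBANCE_CUTOFF_M,
                        d_min: float = 1.0):
        """MSA due to disturbance near roads and mines.

        Cells farther than ``cutoff_m`` from the nearest feature are
        unaffected (MSA = 1).  Distances below ``d_min`` (including
        on-feature cells at distance 0) are floored at ``d_min`` because
        the log curve is undefined at 0.
        """
        d = np.asarray(distance_m, dtype=float)
        if np.any(d < 0.0):
            raise ValueError("distance must be non-negative")
        curve = self.get(group, Driver.DISTURBANCE)
        out = np.ones_like(d)
        within = d <= cutoff_m
        if np.any(within):
            out[within] = curve.evaluate(np.maximum(d[within], d_min), self.log_base)
        if np.ndim(distance_m) == 0:
            return float(out)
        return out

    # -- (de)serialization --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self._curves.values():
            rows.append(
                {
                    "group": c.group.value,
                    "driver": c.driver.value,
                    "landuse_class": c.landuse_class or "",
                    "c0": c.c0,
                    "c1": c.c1,
                    "transform": c.transform,
                    "fixed_msa": "" if c.fixed_msa is None else c.fixed_msa,
                    "covariate_units": c.covariate_units,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, log_base: float = 10.0) -> "RelationshipSet":
        curves = []
        for _, row in df.iterrows():
            lu = row.get("landuse_class", "")
            lu = None if (pd.isna(lu) or lu == "") else str(lu)
            fm = row.get("fixed_msa", "")
            fm = None if (pd.isna(fm) or fm == "") else float(fm)
            curves.append(
                ResponseCurve(
                    group=Group(row["group"]),
                    driver=Driver(row["driver"]),
                    landuse_class=lu,
                    c0=float(row["c0"]) if not pd.isna(row["c0"]) else 0.0,
                    c1=float(row["c1"]) if not pd.isna(row["c1"]) else 0.0,
                    transform=str(row["transform"]),
                    fixed_msa=fm,
                    covariate_units=str(row.get("covariate_units", "none")),
                )
            )
        return cls(curves, log_base=log_base)

    @classmethod
    def from_csv(cls, path: str | Path, log_base: float = 10.0) -> "RelationshipSet":
        return cls.from_frame(pd.read_csv(path), log_base=log_base)


def load_default_relationships(log_base: float = 10.0) -> RelationshipSet:
    """Load the packaged default relationship set.

    The defaults contain the climate, nitrogen, habitat-loss,
    fragmentation and disturbance curves for both species groups,
    including the mine rule (habitat-loss MSA fixed at 0 for mines).
    """
    with resources.files("msabif.data").joinpath("response_curves.csv").open() as fh:
        return RelationshipSet.from_frame(pd.read_csv(fh), log_base=log_base)
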
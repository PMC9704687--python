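"""Synthetic GRM response data with the structure the linking analysis assumes.

The restricted cohort data behind the analyses cannot be shipped, so this
module generates response matrices with the same statistical design: a
single group answering both a fixed anchor scale and a free legacy scale in
one sitting, latent severity drawn from either a normal population or a
two-component normal mixture whose mass concentrates at low severity (a
floor effect, emulating a healthy young cohort).

Defaults reproduce the two study designs: a validation-like sample of 448
persons with the floor-effected mixture, and a development-like sample of
2009 persons with a standard normal trait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .grm import GRMItem, ResponseMatrix, cumulative_prob
from .reference import bsi_items_8a_linked, default_anchor_bank

__all__ = [
    "PopulationSpec",
    "validation_population",
    "development_population",
    "simulate_thetas",
    "simulate_responses",
    "make_linking_fixture",
    "LinkingFixture",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Latent-trait population for simulation.

    ``distribution="normal"`` uses ``means[0], sds[0]``; ``"mixture"`` is a
    two-component normal mixture with mixing weight ``weight`` on the first
    component.
    """

    distribution: str
    n_persons: int
    seed: int
    means: tuple[float, ...] = (0.0,)
    sds: tuple[float, ...] = (1.0,)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.distribution not in ("normal", "mixture"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")
        if self.distribution == "mixture":
            if len(self.means) != 2 or len(self.sds) != 2:
                raise ValueError("mixture needs two means and two sds")
            if not 0 < self.weight < 1:
                raise ValueError("mixing weight must be in (0, 1)")

    @property
    def mean(self) -> float:
        """Analytic population mean."""
        if self.distribution == "normal":
            return self.means[0]
        w = self.weight
        return w * self.means[0] + (1 - w) * self.means[1]

    def to_dict(self) -> dict:
        return {
            "distribution": self.distribution,
            "n_persons": self.n_persons,
            "seed": self.seed,
            "means": list(self.means),
            "sds": list(self.sds),
            "weight": self.weight,
        }


def validation_population(seed: int = 0, n_persons: int = 448) -> PopulationSpec:
    """Floor-effected mixture emulating a young, mostly-asymptomatic cohort."""
    return PopulationSpec(
        distribution="mixture",
        n_persons=n_persons,
        seed=seed,
        means=(-0.8, 0.6),
        sds=(0.7, 0.9),
        weight=0.7,
    )


def development_population(seed: int = 0, n_persons: int = 2009) -> PopulationSpec:
    """Standard normal trait at the development sample's size."""
    return PopulationSpec(distribution="normal", n_persons=n_persons, seed=seed)


def simulate_thetas(spec: PopulationSpec) -> np.ndarray:
    """Draw latent traits; reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_persons
    if spec.distribution == "normal":
        return rng.normal(spec.means[0], spec.sds[0], size=n)
    comp = rng.random(n) >= spec.weight  # 0 = first component
    theta = np.where(
        comp,
        rng.normal(spec.means[1], spec.sds[1], size=n),
        rng.normal(spec.means[0], spec.sds[0], size=n),
    )
    return theta


def simulate_responses(
    thetas: np.ndarray,
    items: Sequence[GRMItem],
    seed: int,
    D: float = 1.0,
    person_ids: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Draw GRM responses: one uniform per cell, X = #{k : u < P(X >= k)}."""
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    n = thetas.size
    cols = []
    for item in items:
        u = rng.random(n)
        x = np.zeros(n, dtype=np.int64)
        for k in range(1, item.n_categories):
            x += (u < cumulative_prob(item, thetas, k, D)).astype(np.int64)
        cols.append(x)
    values = np.column_stack(cols)
    return ResponseMatrix(
        values,
        tuple(it.item_id for it in items),
        tuple(person_ids) if person_ids is not None else (),
    )


@dataclass(frozen=True)
class LinkingFixture:
    """Self-describing simulation bundle: responses plus the generating truth."""

    responses: ResponseMatrix
    items: list[GRMItem]
    thetas: np.ndarray
    spec: PopulationSpec
    seed: int

    @property
    def anchor_items(self) -> list[GRMItem]:
        return [it for it in self.items if it.fixed]

    @property
    def legacy_items(self) -> list[GRMItem]:
        return [it for it in self.items if not it.fixed]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "population": self.spec.to_dict(),
            "n_persons": self.responses.n_persons,
            "anchor_items": [it.item_id for it in self.anchor_items],
            "legacy_items": [it.item_id for it in self.legacy_items],
            "true_parameters": {
                it.item_id: {"slope": it.slope, "thresholds": list(it.thresholds)}
                for it in self.items
            },
        }


def make_linking_fixture(
    anchor_items: Sequence[GRMItem] | None = None,
    legacy_items: Sequence[GRMItem] | None = None,
    spec: PopulationSpec | None = None,
    out_dir: str | Path | None = None,
) -> LinkingFixture:
    """Single-group, single-occasion linking dataset with known truth.

    Defaults: 8 synthetic anchor items (fixed), the six published
    legacy-scale items as generating truth (free), and the floor-effected
    448-person population.  When ``out_dir`` is given, writes
    ``responses.csv``, ``items.csv``, ``thetas.csv`` and ``manifest.json``.
    """
    anchor_items = list(anchor_items) if anchor_items is not None else default_anchor_bank(8)
    legacy_items = (
        list(legacy_items) if legacy_items is not None else bsi_items_8a_linked(fixed=False)
    )
    spec = spec or validation_population()
    items = anchor_items + legacy_items
    thetas = simulate_thetas(spec)
    # derive the response-draw stream from the population seed so one seed
    # fully determines the fixture
    responses = simulate_responses(thetas, items, seed=spec.seed + 1)
    fixture = LinkingFixture(
        responses=responses, items=items, thetas=thetas, spec=spec, seed=spec.seed
    )
    if out_dir is not None:
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_responses(responses, out / "responses.csv")
        _io.write_item_params(items, out / "items.csv")
        np.savetxt(
            out / "thetas.csv",
            np.column_stack([np.arange(thetas.size), thetas]),
            delimiter=",",
            header="person_index,theta",
            comments="",
            fmt=["%d", "%.10f"],
        )
        (out / "manifest.json").write_text(json.dumps(fixture.manifest(), indent=2))
    return fixture
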
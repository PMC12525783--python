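"""Food-group taxonomy: component definitions and reference statistics.

The taxonomy binds intake columns to score components and carries every
scoring constant (cutoffs, DII reference means/SDs and inflammatory effect
scores, plant-group classes).  The packaged default lives in
``data/taxonomy.yaml``; users override it wholesale by passing their own file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

PDI_CLASSES = ("healthy_plant", "less_healthy_plant", "animal")


@dataclass(frozen=True)
class FoodGroupTaxonomy:
    """Parsed taxonomy with per-score component mappings."""

    items: Mapping[str, Mapping]
    ahei: Mapping
    dash: Mapping
    med: Mapping
    dii: Mapping
    pdi: Mapping

    @property
    def n_pdi_groups(self) -> int:
        return len(self.pdi["groups"])


def load_taxonomy(path: str | Path | None = None) -> FoodGroupTaxonomy:
    """Load and validate a taxonomy file (packaged default when ``path=None``)."""
    if path is None:
        source = resources.files("dietfrail.data").joinpath("taxonomy.yaml")
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    tax = FoodGroupTaxonomy(
        items=raw["items"],
        ahei=raw["ahei"],
        dash=raw["dash"],
        med=raw["med"],
        dii=raw["dii"],
        pdi=raw["pdi"],
    )
    _validate(tax)
    return tax


def _validate(tax: FoodGroupTaxonomy) -> None:
    for name, param in tax.dii["parameters"].items():
        if param["ref_sd"] <= 0:
            raise ConfigurationError(f"DII parameter '{name}' has non-positive ref_sd")
    classes = {g: spec["class"] for g, spec in tax.pdi["groups"].items()}
    bad = {g: c for g, c in classes.items() if c not in PDI_CLASSES}
    if bad:
        raise ConfigurationError(f"plant-index group(s) with unknown class: {bad}")
    # Every component item must be a declared intake column.
    def check_items(owner: str, items: Mapping[str, float]) -> None:
        unknown = set(items) - set(tax.items)
        if unknown:
            raise ConfigurationError(f"{owner} references undeclared item(s): {sorted(unknown)}")

    for name, comp in tax.ahei["components"].items():
        check_items(f"AHEI component '{name}'", comp["items"])
    for name, comp in tax.dash["components"].items():
        check_items(f"DASH component '{name}'", comp["items"])
    for name, comp in tax.med["components"].items():
        if comp.get("kind") == "ratio":
            check_items(f"MED component '{name}'", comp["numerator"])
            check_items(f"MED component '{name}'", comp["denominator"])
        else:
            check_items(f"MED component '{name}'", comp["items"])
    check_items("MED alcohol", tax.med["alcohol"]["items"])
    for name, param in tax.dii["parameters"].items():
        check_items(f"DII parameter '{name}'", param["items"])
    for name, group in tax.pdi["groups"].items():
        check_items(f"plant-index group '{name}'", group["items"])


def component_total(intakes: pd.DataFrame, items: Mapping[str, float],
                    owner: str = "component") -> np.ndarray:
    """Weighted sum of intake columns for one component."""
    missing = [c for c in items if c not in intakes.columns]
    if missing:
        raise ConfigurationError(f"{owner} requires missing intake column(s): {missing}")
    total = np.zeros(len(intakes), dtype=float)
    for col, weight in items.items():
        total += intakes[col].to_numpy(dtype=float) * float(weight)
    return total
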
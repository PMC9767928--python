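"""Signed dissipation weights from footprint distances.

A metabolite at reaction distance d from an enzyme gets weight
penalty**(d-1): 1 for direct reactants/products, decaying multiplicatively
per additional reaction step.  Downstream weights are positive, upstream
negative; a metabolite reachable both ways (cycles) gets the arithmetic
mean of the two signed values, so its weight encodes which side dominates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .forest import Forest

__all__ = ["weight_from_distance", "signed_weights", "write_weights", "read_weights"]

DEFAULT_PENALTY = 0.8

WEIGHT_COLUMNS = ["root_id", "species_id", "down_distance", "up_distance", "weight"]


def weight_from_distance(distance: int, penalty: float) -> float:
    """Unsigned dissipation weight penalty**(distance-1).

    Distance 1 (a direct reactant or product) maps to exactly 1.0 for every
    penalty, including 0 (0**0 == 1 here).
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    if not 0.0 <= penalty <= 1.0:
        raise ValueError(f"penalty must be in [0, 1], got {penalty}")
    if distance == 1:
        return 1.0
    return penalty ** (distance - 1)


def _signed(down: int | None, up: int | None, penalty: float) -> float:
    if down is not None and up is not None:
        return (weight_from_distance(down, penalty) - weight_from_distance(up, penalty)) / 2.0
    if down is not None:
        return weight_from_distance(down, penalty)
    if up is not None:
        return -weight_from_distance(up, penalty)
    raise ValueError("species with neither distance should not be present")


def signed_weights(forest: Forest, penalty: float = DEFAULT_PENALTY) -> pd.DataFrame:
    """Signed weight of every (root, species) association in a forest.

    Returns a DataFrame with columns root_id, species_id, down_distance,
    up_distance (nullable integers) and weight in [-1, 1], sorted by
    (root_id, species_id).
    """
    rows = []
    for root in sorted(forest):
        for sid in sorted(forest[root]):
            d = forest[root][sid].get("down")
            u = forest[root][sid].get("up")
            rows.append(
                {
                    "root_id": root,
                    "species_id": sid,
                    "down_distance": d,
                    "up_distance": u,
                    "weight": _signed(d, u, penalty),
                }
            )
    df = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    df["down_distance"] = df["down_distance"].astype("Int64")
    df["up_distance"] = df["up_distance"].astype("Int64")
    return df


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, index=False, float_format="%.12g")


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"root_id": str, "species_id": str})
    df["down_distance"] = df["down_distance"].astype("Int64")
    df["up_distance"] = df["up_distance"].astype("Int64")
    return df
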
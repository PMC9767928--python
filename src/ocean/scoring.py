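"""Footprint scoring: join dissipation weights with differential statistics.

Produces, per enzyme root, a scatter table (x = signed weight, y = t-value,
dot size = |t * weight|) of the metabolites upstream and downstream of the
enzyme, plus an optional scalar imbalance score summarising whether the
footprint shows downstream accumulation relative to upstream.  The
imbalance score is an extension of this package, not part of the original
footprint visualisation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weights import weight_from_distance, DEFAULT_PENALTY

__all__ = [
    "read_mapping",
    "collapse_to_base_names",
    "select_roots",
    "footprint_scatter",
    "imbalance_score",
    "imbalance_scores",
    "plot_scatter",
]

logger = logging.getLogger(__name__)

SCATTER_COLUMNS = ["root_id", "metabolite", "weight", "t_value", "dot_size", "side"]


def read_mapping(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read measured_name -> base_name aliases (many targets per name allowed)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("measured_name", "base_name"):
        if col not in df.columns:
            raise ValueError(f"mapping table: missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        if not row.base_name:
            raise ValueError(f"empty mapping target for {row.measured_name!r}")
        mapping.setdefault(row.measured_name, []).append(row.base_name)
    return {k: tuple(dict.fromkeys(v)) for k, v in mapping.items()}


def _default_base_name(species_id: str) -> str:
    return species_id.rsplit("_", 1)[0] if "_" in species_id else species_id


def collapse_to_base_names(
    weights: pd.DataFrame,
    base_names: Mapping[str, str] | None = None,
    penalty: float = DEFAULT_PENALTY,
) -> pd.DataFrame:
    """Collapse compartment duplicates to base names by the min-distance rule.

    For each (root, base_name) the minimal down- and up-distance over all
    compartment species is kept (per direction, before signing/averaging) and
    the signed weight recomputed.  Ties are resolved to the lexicographically
    first species_id; provenance columns record the winners.  Without an
    explicit species->base map, the suffix convention ``name_c`` is used.
    """
    df = weights.copy()
    if base_names is None:
        df["base_name"] = df["species_id"].map(_default_base_name)
    else:
        df["base_name"] = df["species_id"].map(dict(base_names))
        if df["base_name"].isna().any():
            missing = sorted(df.loc[df["base_name"].isna(), "species_id"].unique())
            raise KeyError(f"species without base name: {missing}")
    df = df.sort_values(["root_id", "base_name", "species_id"], kind="stable")

    rows = []
    for (root, base), grp in df.groupby(["root_id", "base_name"], sort=True):
        entry = {"root_id": root, "base_name": base}
        for direction in ("down", "up"):
            col = f"{direction}_distance"
            valid = grp.dropna(subset=[col])
            if len(valid):
                best = valid.loc[valid[col].idxmin()]  # idxmin: first = lexicographic
                entry[col] = int(best[col])
                entry[f"{direction}_species"] = best["species_id"]
            else:
                entry[col] = pd.NA
                entry[f"{direction}_species"] = ""
        d, u = entry["down_distance"], entry["up_distance"]
        terms = []
        if d is not pd.NA:
            terms.append(weight_from_distance(d, penalty))
        if u is not pd.NA:
            terms.append(-weight_from_distance(u, penalty))
        entry["weight"] = sum(terms) / len(terms)
        rows.append(entry)
    out = pd.DataFrame(
        rows,
        columns=["root_id", "base_name", "down_distance", "up_distance",
                 "down_species", "up_species", "weight"],
    )
    out["down_distance"] = out["down_distance"].astype("Int64")
    out["up_distance"] = out["up_distance"].astype("Int64")
    return out


def _root_members(root_id: str) -> set[str]:
    return set(root_id.split("@", 1)[0].split("+"))


def select_roots(root_ids: Sequence[str], selector: str) -> list[str]:
    """Resolve an enzyme selector to instance roots.

    Matches exact instance ids or any instance whose catalyst contains the
    selector as a member gene.  Raises LookupError when nothing matches.
    """
    hits = sorted(
        r for r in set(root_ids) if r == selector or selector in _root_members(r)
    )
    if not hits:
        raise LookupError(f"selector {selector!r} matches no enzyme instance")
    return hits


def _side(down, up) -> str:
    if down is not pd.NA and up is not pd.NA and not pd.isna(down) and not pd.isna(up):
        return "both"
    if down is not pd.NA and not pd.isna(down):
        return "downstream"
    return "upstream"


def footprint_scatter(
    weights: pd.DataFrame,
    stats: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]] | None,
    root_selector: str,
) -> pd.DataFrame:
    """Scatter table for an enzyme's footprint.

    ``weights`` must be base-name collapsed (see :func:`collapse_to_base_names`).
    Each measured metabolite maps through ``mapping`` (identity when None) to
    network base names; a many-to-one alias resolves to its minimum-distance
    target.  Rows: root_id, metabolite (measured name), weight (x), t_value
    (y), dot_size = |t * weight|, side; sorted by dot_size descending.
    Measured metabolites without a weight in the footprint are omitted (count
    logged).
    """
    roots = select_roots(weights["root_id"].tolist(), root_selector)
    stats = stats.set_index("metabolite") if "metabolite" in stats.columns else stats
    rows = []
    omitted = 0
    for root in roots:
        w_root = weights.loc[weights["root_id"] == root].set_index("base_name")
        for measured, t_value in stats["t_value"].items():
            targets = list(mapping.get(measured, ())) if mapping is not None else [measured]
            targets = [b for b in targets if b in w_root.index]
            if not targets:
                omitted += 1
                continue
            # many-to-one alias: the closest network species wins
            def _min_dist(b: str) -> float:
                e = w_root.loc[b]
                cands = [x for x in (e["down_distance"], e["up_distance"]) if not pd.isna(x)]
                return min(cands) if cands else np.inf
            best = min(targets, key=lambda b: (_min_dist(b), b))
            entry = w_root.loc[best]
            weight = float(entry["weight"])
            rows.append(
                {
                    "root_id": root,
                    "metabolite": measured,
                    "weight": weight,
                    "t_value": float(t_value),
                    "dot_size": abs(float(t_value) * weight),
                    "side": _side(entry["down_distance"], entry["up_distance"]),
                }
            )
    if omitted:
        logger.info("footprint_scatter: %d measured metabolites outside footprint", omitted)
    out = pd.DataFrame(rows, columns=SCATTER_COLUMNS)
    return out.sort_values(
        ["dot_size", "root_id", "metabolite"], ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)


def imbalance_score(
    weights: pd.DataFrame,
    stats: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]] | None,
    root_selector: str,
) -> float:
    """Weight-normalised signed summary of a footprint.

    score = sum_m w(root, m) * t(m) / sum_m |w(root, m)| over mapped
    metabolites; positive means downstream accumulation relative to
    upstream, 0 for an empty intersection.  When the selector resolves to
    several instances, the mean of their (identical-by-construction or
    near-identical) scores is returned.
    """
    scatter = footprint_scatter(weights, stats, mapping, root_selector)
    if scatter.empty:
        return 0.0
    per_root = []
    for _, grp in scatter.groupby("root_id"):
        denom = grp["weight"].abs().sum()
        per_root.append(
            float((grp["weight"] * grp["t_value"]).sum() / denom) if denom > 0 else 0.0
        )
    return float(np.mean(per_root))


def imbalance_scores(
    weights: pd.DataFrame,
    stats: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Imbalance score of every root in a weight table, sorted by |score| desc."""
    scores = {}
    for root in sorted(weights["root_id"].unique()):
        scores[root] = imbalance_score(weights, stats, mapping, root)
    out = pd.Series(scores, name="imbalance_score")
    return out.reindex(out.abs().sort_values(ascending=False, kind="stable").index)


def plot_scatter(scatter: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render one footprint scatter (x = signed weight, y = t, size = |t*w|)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    if not scatter.empty:
        ax.scatter(
            scatter["weight"], scatter["t_value"],
            s=20 + 60 * scatter["dot_size"] / max(scatter["dot_size"].max(), 1e-9),
            alpha=0.7, edgecolor="k", linewidth=0.3,
        )
        top = scatter.nlargest(8, "dot_size")
        for _, row in top.iterrows():
            ax.annotate(row["metabolite"], (row["weight"], row["t_value"]),
                        fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.axvline(0, color="grey", lw=0.5)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("signed weighted distance (upstream < 0 < downstream)")
    ax.set_ylabel("t-value")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
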
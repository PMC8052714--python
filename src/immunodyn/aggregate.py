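"""Sigma-summation views, cohort comparison, and flow-diagram export.

Quads collapse hierarchically by summing occurrence counts over like
components: dropping the LSV tag gives Triplets (modulator, source,
target); dropping one further role gives the three Doublet views
(modulator-source, source-target, target-modulator); collapsing to a single
role gives Singlets.  Every level conserves the grand total of Quad values.

For presentation-exact sums the raw integer counts are summed first and
normalized once — summing already-rounded 2-dp values can drift by a unit
in the last place.

Cohorts are compared by averaging quad tables over participants (absent
quads count as zero) and subtracting elementwise; the signed difference
splits into positive (first cohort more active) and negative parts.  Flow
diagrams reduce a quad or difference table to modulator-source doublets
(edges) and singlets (nodes), written as Graphviz DOT plus a JSON twin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .knowledge import NA

__all__ = [
    "DOUBLET_VIEWS",
    "SINGLET_ROLES",
    "CohortComparison",
    "sum_triplets",
    "sum_doublets",
    "sum_singlets",
    "average_cohort",
    "diff_cohorts",
    "top_doublets",
    "build_flow_graph",
    "export_flow",
]

QUAD_KEY = ["modulator", "source", "target", "lsv"]
DOUBLET_VIEWS = {
    "modulator_source": ["modulator", "source"],
    "source_target": ["source", "target"],
    "target_modulator": ["target", "modulator"],
}
SINGLET_ROLES = ("modulator", "source", "target", "lsv")


def _value_column(qt: pd.DataFrame) -> str:
    if "normalized" in qt.columns:
        return "normalized"
    if "raw_count" in qt.columns:
        return "raw_count"
    raise ValueError("quad table has neither 'normalized' nor 'raw_count'")


def _grouped(qt: pd.DataFrame, key: list[str],
             max_count: int | None) -> pd.DataFrame:
    if max_count is not None and "raw_count" in qt.columns:
        out = qt.groupby(key, sort=True)["raw_count"].sum().reset_index()
        out["value"] = 100.0 * out["raw_count"] / max_count
        return out
    col = _value_column(qt)
    return (qt.groupby(key, sort=True)[col].sum()
              .rename("value").reset_index())


def sum_triplets(qt: pd.DataFrame, max_count: int | None = None
                 ) -> pd.DataFrame:
    """Collapse the LSV dimension: value per (modulator, source, target).

    With ``max_count`` given and integer raw counts present, sums go
    through the raw counts and are normalized once (exact 2-dp
    presentation); otherwise the normalized values are summed directly.
    """
    return _grouped(qt, ["modulator", "source", "target"], max_count)


def sum_doublets(qt: pd.DataFrame, view: str = "modulator_source",
                 max_count: int | None = None) -> pd.DataFrame:
    """Collapse to one of the three 2-D doublet views."""
    if view not in DOUBLET_VIEWS:
        raise ValueError(f"unknown doublet view {view!r}; "
                         f"choose from {sorted(DOUBLET_VIEWS)}")
    return _grouped(qt, DOUBLET_VIEWS[view], max_count)


def sum_singlets(qt: pd.DataFrame, role: str = "modulator",
                 max_count: int | None = None) -> pd.DataFrame:
    """Collapse to a single role; ``n.a.`` forms its own modulator key."""
    if role not in SINGLET_ROLES:
        raise ValueError(f"unknown singlet role {role!r}; "
                         f"choose from {SINGLET_ROLES}")
    return _grouped(qt, [role], max_count)


def average_cohort(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean normalized quad table over participants.

    The mean runs over the union of quad keys with absent participants
    contributing zero; the participant count is recorded in
    ``df.attrs["n_participants"]``.
    """
    if not tables:
        raise ValueError("no quad tables to average")
    frames = []
    for t in tables:
        col = _value_column(t)
        frames.append(t[QUAD_KEY + [col]].rename(columns={col: "value"}))
    allq = pd.concat(frames, ignore_index=True)
    out = (allq.groupby(QUAD_KEY, sort=True)["value"].sum() / len(tables))
    out = out.rename("normalized").reset_index()
    out.attrs["n_participants"] = len(tables)
    return out


@dataclass
class CohortComparison:
    """Signed elementwise difference of two averaged quad tables."""

    mean_a: pd.DataFrame
    mean_b: pd.DataFrame
    diff: pd.DataFrame        # columns QUAD_KEY + ["normalized"] (signed)

    @property
    def positive(self) -> pd.DataFrame:
        return self.diff[self.diff["normalized"] > 0].reset_index(drop=True)

    @property
    def negative(self) -> pd.DataFrame:
        return self.diff[self.diff["normalized"] < 0].reset_index(drop=True)


def diff_cohorts(a: pd.DataFrame, b: pd.DataFrame) -> CohortComparison:
    """Elementwise ``a - b`` over the union of quad keys."""
    ca, cb = _value_column(a), _value_column(b)
    left = a.set_index(QUAD_KEY)[ca]
    right = b.set_index(QUAD_KEY)[cb]
    diff = left.sub(right, fill_value=0.0).rename("normalized").reset_index()
    diff = diff.sort_values(QUAD_KEY, kind="stable").reset_index(drop=True)
    return CohortComparison(a, b, diff)


def top_doublets(cmp_or_table: CohortComparison | pd.DataFrame,
                 view: str = "modulator_source", n: int = 10) -> pd.DataFrame:
    """The ``n`` doublets with the greatest (signed) value, descending.

    Ties break deterministically by key order.
    """
    qt = (cmp_or_table.diff if isinstance(cmp_or_table, CohortComparison)
          else cmp_or_table)
    d = sum_doublets(qt, view)
    key = DOUBLET_VIEWS[view]
    d = d.sort_values(["value"] + key, ascending=[False] + [True] * len(key),
                      kind="stable")
    return d.head(n).reset_index(drop=True)


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def build_flow_graph(cmp_or_table: "CohortComparison | pd.DataFrame",
                     view: str = "modulator_source",
                     top_sources: int = 10,
                     top_modulators: int = 15) -> nx.DiGraph:
    """Reduce a quad (or signed difference) table to a flow graph.

    Modulator singlets become octagon nodes (cytokines and ``n.a.``),
    source singlets circle nodes (cells); node ``size`` carries the singlet
    value and edge ``width`` the doublet value.  Signed tables color edges
    by sign (positive green, negative red).  Only the ``top_sources``
    largest sources and ``top_modulators`` largest modulators (plus
    ``n.a.``) are kept.
    """
    if view != "modulator_source":
        raise ValueError("flow diagrams use the modulator_source view")
    qt = (cmp_or_table.diff if isinstance(cmp_or_table, CohortComparison)
          else cmp_or_table)
    signed = bool(len(qt)) and bool((qt[_value_column(qt)] < 0).any())
    doublets = sum_doublets(qt, view)
    mod_singlets = sum_singlets(qt, "modulator")
    src_singlets = sum_singlets(qt, "source")

    def keep_top(df: pd.DataFrame, role: str, k: int) -> set[str]:
        df = df.assign(rank_mag=df["value"].abs())
        df = df.sort_values(["rank_mag", role], ascending=[False, True],
                            kind="stable")
        return set(df.head(k)[role])

    keep_mod = keep_top(mod_singlets[mod_singlets["modulator"] != NA],
                        "modulator", top_modulators)
    if (mod_singlets["modulator"] == NA).any():
        keep_mod |= {NA}
    keep_src = keep_top(src_singlets, "source", top_sources)

    g = nx.DiGraph(view=view, signed=signed)
    mods = mod_singlets.set_index("modulator")["value"]
    srcs = src_singlets.set_index("source")["value"]
    for m in sorted(keep_mod):
        g.add_node(f"M::{m}", label=m, role="modulator", shape="octagon",
                   size=float(mods.get(m, 0.0)))
    for s in sorted(keep_src):
        g.add_node(f"S::{s}", label=s, role="source", shape="circle",
                   size=float(srcs.get(s, 0.0)))
    for row in doublets.itertuples(index=False):
        if row.modulator in keep_mod and row.source in keep_src:
            color = ("black" if not signed
                     else ("green" if row.value > 0
                           else "red" if row.value < 0 else "gray"))
            g.add_edge(f"M::{row.modulator}", f"S::{row.source}",
                       width=float(row.value), color=color)
    return g


def export_flow(cmp_or_table, out: str | Path,
                view: str = "modulator_source",
                top_sources: int = 10, top_modulators: int = 15,
                size_scale: float = 1.0) -> nx.DiGraph:
    """Write a flow diagram as Graphviz DOT (``out``) plus a JSON twin.

    ``size_scale`` linearly maps occurrence-count totals to display sizes;
    reuse one scale across diagrams meant for side-by-side comparison.
    Output is deterministic (sorted nodes/edges, fixed attribute names), so
    reruns on identical inputs are byte-identical.
    """
    g = build_flow_graph(cmp_or_table, view, top_sources, top_modulators)
    out = Path(out)
    lines = ["digraph flow {"]
    for node in sorted(g.nodes):
        d = g.nodes[node]
        lines.append(
            f'  "{node}" [label="{d["label"]} ({_fmt(d["size"])})" '
            f'shape={d["shape"]} width={_fmt(abs(d["size"]) * size_scale)}];')
    for u, v in sorted(g.edges):
        d = g.edges[u, v]
        lines.append(
            f'  "{u}" -> "{v}" [penwidth={_fmt(abs(d["width"]) * size_scale)}'
            f' color={d["color"]} label="{_fmt(d["width"])}"];')
    lines.append("}")
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    twin = nx.node_link_data(g, edges="edges")
    out.with_suffix(".json").write_text(
        json.dumps(twin, indent=1, sort_keys=True), encoding="utf-8")
    return g
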
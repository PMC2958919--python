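"""Gene-tree / species concordance and the causes of discordance.

Species that are exclusive clades in the gene tree are *concordant* with the
species classification.  For nonmonophyletic species, three criteria are
combined to suggest the likely cause of the discordance:

1. **coalescence depth** — the relative height at which discordant lineages
   join heterospecific lineages: deep joins point to retained ancestral
   polymorphism (incomplete lineage sorting), shallow joins to recent gene
   transfer;
2. **admixture evidence** — foreign ancestry in nuclear multilocus data from
   the pairwise admixture scans;
3. **geography** — whether carriers of shared haplotypes concentrate near a
   range boundary (reported as a score, never a hard gate, since a boundary
   concentration can also reflect a pre-existing cline).

The decision table: deep coalescence with no nuclear admixture is classified
incomplete-lineage-sorting; shallow coalescence with admixture in
geographically adjacent individuals is classified
recent-divergence-or-introgression (deliberately unresolved further — the
two are not distinguishable from these data alone); conflicting signals are
labelled ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GeneTree, SpecimenTable

__all__ = [
    "MonophylyReport",
    "DiscordanceEvent",
    "DiscordanceReport",
    "Thresholds",
    "assess_monophyly",
    "coalescence_depth_profile",
    "classify_discordance",
    "species_map_from_tips",
]


@dataclass
class Thresholds:
    """Explicit numeric conventions behind the qualitative criteria."""

    depth: float = 0.5        # relative coalescence depth >= this is "deep"
    admixture: float = 0.10   # foreign ancestry >= this is "admixture evidence"


@dataclass
class MonophylyReport:
    """Per-species monophyly status with intruder and outlier tips.

    ``intruders``: foreign tips inside the species' MRCA clade.
    ``outliers``: the species' own tips outside its core clade (the maximal
    clade of conspecific tips holding the plurality of the species' tips).
    """

    status: dict[str, str]
    intruders: dict[str, list[str]]
    outliers: dict[str, list[str]]

    def monophyletic(self) -> list[str]:
        return sorted(s for s, st in self.status.items() if st == "monophyletic")

    def nonmonophyletic(self) -> list[str]:
        return sorted(s for s, st in self.status.items() if st != "monophyletic")


@dataclass
class DiscordanceEvent:
    """One discordant coalescence: the tips involved and the relative height
    (0 = tips, 1 = root) of the smallest clade joining them with
    heterospecific lineages."""

    tips: list[str]
    relative_depth: float


@dataclass
class DiscordanceReport:
    table: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)


def species_map_from_tips(labels: Iterable[str], sep: str = "_") -> dict[str, str]:
    """Species mapping for tips named ``<species><sep><index>``."""
    return {lab: lab.rsplit(sep, 1)[0] for lab in labels}


def _species_map(
    meta: SpecimenTable | Mapping[str, str], labels: Sequence[str]
) -> dict[str, str]:
    if isinstance(meta, SpecimenTable):
        mapping = meta.species_of()
        known = set(mapping) | set(mapping.values())
    else:
        mapping = dict(meta)
        known = set(mapping)
    out = {}
    for lab in labels:
        if lab in mapping:
            out[lab] = mapping[lab]
        elif isinstance(meta, SpecimenTable) and lab in known:
            out[lab] = lab  # tip named directly by species label
        else:
            raise ValueError(f"tip {lab!r} maps to no specimen or species")
    return out


def _tip_depth_below(node: dendropy.Node, label: str) -> float:
    """Path length from ``node`` down to the named tip (0 if not below it)."""
    for leaf in node.leaf_iter():
        if leaf.taxon.label == label:
            d = 0.0
            v = leaf
            while v is not node:
                d += v.edge.length or 0.0
                v = v.parent_node
            return d
    return 0.0


def _node_height(node: dendropy.Node) -> float:
    """Maximum path length from a node down to its descendant leaves."""
    best = 0.0
    for leaf in node.leaf_iter():
        d = 0.0
        v = leaf
        while v is not node:
            d += v.edge.length or 0.0
            v = v.parent_node
        best = max(best, d)
    return best


def assess_monophyly(
    t: GeneTree, meta: SpecimenTable | Mapping[str, str]
) -> MonophylyReport:
    """Monophyly status of every species with tips in the tree.

    A species is monophyletic when its MRCA clade contains no foreign tips;
    otherwise it is paraphyletic when the intruding tips form a single clade
    and polyphyletic when they do not.  Outlier tips are measured against the
    maximal all-conspecific clade containing the plurality of the species'
    tips.
    """
    tree = t.tree
    labels = t.tip_labels()
    sp = _species_map(meta, labels)
    by_species: dict[str, list[str]] = {}
    for lab in labels:
        by_species.setdefault(sp[lab], []).append(lab)

    status: dict[str, str] = {}
    intruders: dict[str, list[str]] = {}
    outliers: dict[str, list[str]] = {}
    for species, tips in by_species.items():
        if len(tips) == 1:
            status[species] = "monophyletic"
            intruders[species] = []
            outliers[species] = []
            continue
        mrca = tree.mrca(taxon_labels=tips)
        clade = [l.taxon.label for l in mrca.leaf_iter()]
        foreign = sorted(set(clade) - set(tips))
        if not foreign:
            status[species] = "monophyletic"
            intruders[species] = []
            outliers[species] = []
            continue
        intruders[species] = foreign
        # core clade: all-conspecific clade with the most tips of this species
        best_core: set[str] = set()
        for node in tree.preorder_node_iter():
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves <= set(tips) and len(leaves) > len(best_core):
                best_core = leaves
        outliers[species] = sorted(set(tips) - best_core)
        foreign_mrca = (
            tree.mrca(taxon_labels=foreign) if len(foreign) > 1
            else next(l for l in tree.leaf_node_iter() if l.taxon.label == foreign[0])
        )
        foreign_clade = {l.taxon.label for l in foreign_mrca.leaf_iter()}
        status[species] = (
            "paraphyletic" if foreign_clade == set(foreign) else "polyphyletic"
        )
    return MonophylyReport(status, intruders, outliers)


def coalescence_depth_profile(
    t: GeneTree,
    meta: SpecimenTable | Mapping[str, str],
    species: str,
    exclude: Iterable[str] = (),
) -> list[DiscordanceEvent]:
    """Relative depths of the discordant coalescences involving a species.

    For every discordant tip (an outlier tip of the species, or a foreign tip
    intruding into its MRCA clade) the smallest clade joining it with
    heterospecific lineages is found by walking rootward; the event depth is
    that clade's height (maximum node-to-leaf path — no ultrametricity
    assumed) divided by the root height.  Tips listed in ``exclude``
    (outgroups) do not enter the normalization: heights are taken relative to
    the MRCA of the remaining (ingroup) tips, so a long outgroup stem cannot
    dilute the relative depths.  Events sharing a joining clade are merged.
    """
    tree = t.tree
    labels = t.tip_labels()
    sp = _species_map(meta, labels)
    report = assess_monophyly(t, meta)
    if report.status.get(species) == "monophyletic":
        return []
    if species not in report.status:
        raise ValueError(f"species {species!r} has no tips in the tree")
    ingroup = [lab for lab in labels if lab not in set(exclude)]
    if len(ingroup) < 2:
        raise ValueError("fewer than 2 ingroup tips after exclusions")
    apex = (tree.mrca(taxon_labels=ingroup)
            if len(ingroup) < len(labels) else tree.seed_node)
    root_h = max(_tip_depth_below(apex, lab) for lab in ingroup)
    if root_h <= 0:
        raise ValueError("zero root height; branch lengths required")
    discordant = report.outliers[species] + report.intruders[species]
    leaf_by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    events: dict[int, DiscordanceEvent] = {}
    for lab in discordant:
        own = sp[lab]
        node = leaf_by_label[lab]
        while node.parent_node is not None:
            node = node.parent_node
            leaves = [l.taxon.label for l in node.leaf_iter()]
            if any(sp[x] != own for x in leaves):
                break
        key = id(node)
        if key in events:
            if lab not in events[key].tips:
                events[key].tips.append(lab)
        else:
            events[key] = DiscordanceEvent([lab], _node_height(node) / root_h)
    return sorted(events.values(), key=lambda e: -e.relative_depth)


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def _geo_score(
    carriers: list[str], members: list[str], coords: Mapping[str, tuple[float, float]]
) -> tuple[float, float]:
    """(mean pairwise km between carriers, range span km of the species)."""

    def mean_pair(ids: list[str]) -> float:
        pts = [coords[i] for i in ids if i in coords]
        if len(pts) < 2:
            return float("nan")
        ds = [
            _haversine_km(*pts[i], *pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        return float(np.mean(ds))

    def span(ids: list[str]) -> float:
        pts = [coords[i] for i in ids if i in coords]
        if len(pts) < 2:
            return float("nan")
        return max(
            _haversine_km(*pts[i], *pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        )

    return mean_pair(carriers), span(members)


def classify_discordance(
    mono: MonophylyReport,
    depths: Mapping[str, Sequence[DiscordanceEvent] | Sequence[float]],
    admix: Mapping[str, float | pd.DataFrame] | None,
    meta: SpecimenTable | Mapping[str, str] | None = None,
    thresholds: Thresholds | None = None,
) -> DiscordanceReport:
    """Combine the three criteria into a per-species discordance label.

    ``depths`` maps each nonmonophyletic species to its coalescence events
    (or bare relative depths); ``admix`` maps species to the maximum foreign
    ancestry observed among its individuals and geographic neighbours in the
    pairwise admixture scans (a float, or the scan's report table).  A
    species with missing admixture results is labelled ambiguous with a
    reason.  The function is pure: identical inputs give identical labels.
    """
    th = thresholds or Thresholds()
    coords = meta.coordinates_of() if isinstance(meta, SpecimenTable) else {}
    sp_members: dict[str, list[str]] = {}
    if isinstance(meta, SpecimenTable):
        for sid, s in meta.species_of().items():
            sp_members.setdefault(s, []).append(sid)

    rows = []
    for species in sorted(mono.status):
        st = mono.status[species]
        row = dict(
            species=species,
            status=st,
            relative_depth=float("nan"),
            foreign_ancestry=float("nan"),
            carrier_mean_km=float("nan"),
            range_span_km=float("nan"),
            label="concordant",
            reason="",
        )
        if st == "monophyletic":
            rows.append(row)
            continue
        ev = depths.get(species, [])
        dvals = [
            e.relative_depth if isinstance(e, DiscordanceEvent) else float(e)
            for e in ev
        ]
        if not dvals:
            row["label"] = "ambiguous"
            row["reason"] = "no depth profile supplied"
            rows.append(row)
            continue
        depth = float(np.median(dvals))
        row["relative_depth"] = depth
        a = admix.get(species) if admix is not None else None
        if a is None:
            row["label"] = "ambiguous"
            row["reason"] = "no admixture results for this species"
            rows.append(row)
            continue
        if isinstance(a, pd.DataFrame):
            a = float(a["foreign_ancestry"].max())
        row["foreign_ancestry"] = float(a)
        deep = depth >= th.depth
        admixed = a >= th.admixture
        if deep and not admixed:
            row["label"] = "incomplete-lineage-sorting"
        elif not deep and admixed:
            row["label"] = "recent-divergence-or-introgression"
        else:
            row["label"] = "ambiguous"
            row["reason"] = (
                "deep coalescence with admixture" if deep else
                "shallow coalescence without admixture"
            )
        carriers = [
            t for t in mono.outliers[species] + mono.intruders[species] if t in coords
        ]
        if carriers and species in sp_members:
            cm, span = _geo_score(carriers, sp_members[species], coords)
            row["carrier_mean_km"] = cm
            row["range_span_km"] = span
        rows.append(row)
    return DiscordanceReport(pd.DataFrame(rows), th)
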
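"""Haplogroup scoring against a defining-variant tree.

The tree dialect is a TSV of ``node, parent, defining_variants`` where the
variants column is a comma-separated list of forensic notation tokens.
A trailing ``!`` marks a back-mutation: the expected state at that position
is the ancestral (reference) allele, and a query matches it by carrying no
variant there.  Nodes are scored by the fraction of cumulative root-to-node
defining variants present in the query.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .refhap import (
    DEFAULT_IGNORE,
    CircularReference,
    Haplotype,
    Variant,
    _ignore_matches,
    parse_notation,
)


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    defining_variants: tuple[Variant, ...]


@dataclass
class HaplogroupScore:
    name: str
    expected: int
    matched: int
    missing: list[str]
    extra_private: list[str]
    #: query variants explained by derived path variants / counted query size
    query_coverage: float = 0.0

    @property
    def fraction(self) -> float:
        return 1.0 if self.expected == 0 else self.matched / self.expected

    @property
    def rank_score(self) -> float:
        """Symmetric match score: mean of path fraction and query coverage.

        Ranking by the path fraction alone would let a perfect shallow
        ancestor outrank a near-perfect deeper node; averaging in the share
        of the query explained restores specificity, as haplogroup callers
        conventionally do.
        """
        return (self.fraction + self.query_coverage) / 2.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "expected": self.expected,
            "matched": self.matched,
            "fraction": self.fraction,
            "query_coverage": self.query_coverage,
            "rank_score": self.rank_score,
            "missing": self.missing,
            "extra_private": self.extra_private,
        }


class HaplogroupTree:
    """A rooted, acyclic collection of haplogroup nodes."""

    def __init__(self, nodes: Iterable[HaplogroupNode]) -> None:
        self.nodes = {n.name: n for n in nodes}
        if not self.nodes:
            raise TreeError("empty haplogroup tree")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0].name
        for n in self.nodes.values():
            if n.parent is not None and n.parent not in self.nodes:
                raise TreeError(f"node {n.name}: unknown parent {n.parent}")
        # reachability + cycle check
        for name in self.nodes:
            self.path_to(name)

    def path_to(self, name: str) -> list[HaplogroupNode]:
        """Nodes from the root down to ``name``."""
        if name not in self.nodes:
            raise TreeError(f"unknown haplogroup node {name!r}")
        path: list[HaplogroupNode] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise TreeError(f"cycle in tree at node {cur}")
            seen.add(cur)
            node = self.nodes[cur]
            path.append(node)
            cur = node.parent
        return list(reversed(path))

    def path_variants(self, name: str) -> dict[tuple[int, int], Variant]:
        """Cumulative defining variants on the root-to-node path.

        A deeper definition at the same slot (e.g. a back-mutation) overrides
        the shallower one.
        """
        out: dict[tuple[int, int], Variant] = {}
        for node in self.path_to(name):
            for v in node.defining_variants:
                out[v.slot] = v
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplogroupTree":
        nodes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["node", "parent", "defining_variants"]:
                raise TreeError(f"{path}: bad tree header {header}")
            for line in fh:
                if not line.strip():
                    continue
                name, parent, var_field = (line.rstrip("\n").split("\t") + [""])[:3]
                variants = tuple(
                    parse_notation(tok)
                    for tok in var_field.split(",")
                    if tok.strip()
                )
                nodes.append(HaplogroupNode(name, parent or None, variants))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tparent\tdefining_variants\n")
            for n in self.nodes.values():
                toks = ",".join(v.notation() for v in n.defining_variants)
                fh.write(f"{n.name}\t{n.parent or ''}\t{toks}\n")


def _variant_matches(query_by_slot: dict[tuple[int, int], Variant], v: Variant) -> bool:
    q = query_by_slot.get(v.slot)
    if v.back_mutation:
        return q is None  # expected state is the ancestral allele
    return q is not None and q.alt_allele == v.alt_allele and q.kind == v.kind


def score_haplogroups(
    hap: Haplotype,
    tree: HaplogroupTree,
    ignore: Iterable[str] = DEFAULT_IGNORE,
) -> list[HaplogroupScore]:
    """Score every tree node by matched/expected cumulative defining variants.

    Ranking: symmetric rank score desc, then expected desc (deeper, more
    specific node wins ties), then name.  A query back-mutation relative to a
    defining variant counts as missing.
    """
    query_by_slot = {v.slot: v for v in hap.variants}
    counted_query = [v for v in hap.variants if not _ignore_matches(v, ignore)]
    n_query = len(counted_query)
    all_path_notations: set[str] = set()
    for name in tree.nodes:
        for v in tree.path_variants(name).values():
            all_path_notations.add(v.notation().rstrip("!"))
    extra = [
        v.notation()
        for v in hap.variants
        if v.notation() not in all_path_notations and not _ignore_matches(v, ignore)
    ]
    scores = []
    for name in tree.nodes:
        path = tree.path_variants(name)
        matched = sum(1 for v in path.values() if _variant_matches(query_by_slot, v))
        missing = sorted(
            v.notation() for v in path.values()
            if not _variant_matches(query_by_slot, v)
        )
        explained = sum(
            1 for v in path.values()
            if not v.back_mutation and _variant_matches(query_by_slot, v)
        )
        coverage = explained / n_query if n_query else 1.0
        scores.append(
            HaplogroupScore(name, len(path), matched, missing, list(extra), coverage)
        )
    scores.sort(key=lambda s: (-s.rank_score, -s.expected, s.name))
    return scores


def private_mutations(
    hap: Haplotype,
    best: HaplogroupScore,
    tree: HaplogroupTree,
    ignore: Iterable[str] = DEFAULT_IGNORE,
) -> list[Variant]:
    """Query variants not among the best node's path-defining variants."""
    path_notations = {
        v.notation() for v in tree.path_variants(best.name).values()
    }
    return [
        v for v in hap.variants
        if v.notation() not in path_notations and not _ignore_matches(v, ignore)
    ]


def diagnostic_positions(
    tree: HaplogroupTree, node: str, ref: CircularReference
) -> list[tuple[int, str]]:
    """(position, expected allele) for substitution defining variants on the
    root-to-node path; back-mutations expect the reference allele; insertion
    and deletion defining variants are excluded with a warning."""
    sites: list[tuple[int, str]] = []
    for v in sorted(tree.path_variants(node).values(), key=lambda v: v.slot):
        if v.kind != "substitution":
            warnings.warn(
                f"diagnostic position set for {node}: excluding non-substitution "
                f"defining variant {v.notation()}",
                stacklevel=2,
            )
            continue
        allele = ref.base_at(v.position) if v.back_mutation else v.alt_allele
        sites.append((v.position, allele))
    return sites


def write_score_report(scores: Sequence[HaplogroupScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in scores], fh, indent=1)


def format_score_report(scores: Sequence[HaplogroupScore], top: int = 5) -> str:
    lines = ["rank\tnode\tscore\tmatched/expected\tmissing"]
    for i, s in enumerate(scores[:top], start=1):
        lines.append(
            f"{i}\t{s.name}\t{s.fraction:.3f}\t{s.matched}/{s.expected}\t"
            + (",".join(s.missing) or "-")
        )
    return "\n".join(lines)
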
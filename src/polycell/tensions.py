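"""Interfacial tension tables.

A :class:`TensionTable` maps an unordered pair of region *types* (cell type
labels, or the medium label) to the net interfacial tension gamma acting along
edges of that class.  Homotypic interfaces use the pair ``(t, t)``.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Tuple

from .mesh import MEDIUM, Tissue


class TensionTable:
    """Symmetric map from region-type pairs to interfacial tension (gamma >= 0)."""

    def __init__(self, values: Mapping[Tuple[str, str], float] | None = None):
        self._map: Dict[frozenset, float] = {}
        if values:
            for (a, b), g in values.items():
                self.set(a, b, g)

    @staticmethod
    def _key(a: str, b: str) -> frozenset:
        return frozenset({a, b})

    def set(self, a: str, b: str, gamma: float) -> None:
        g = float(gamma)
        if g < 0:
            raise ValueError(f"tension for ({a}, {b}) must be >= 0, got {g}")
        self._map[self._key(a, b)] = g

    def get(self, a: str, b: str) -> float:
        try:
            return self._map[self._key(a, b)]
        except KeyError:
            raise KeyError(f"no tension defined for interface ({a}, {b})") from None

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return self._key(*pair) in self._map

    def items(self) -> Iterable[Tuple[Tuple[str, str], float]]:
        for key, g in sorted(self._map.items(),
                             key=lambda kv: tuple(sorted(kv[0]))):
            pair = tuple(sorted(key))
            if len(pair) == 1:
                pair = (pair[0], pair[0])
            yield pair, g  # type: ignore[misc]

    def validate_total(self, tissue: Tissue) -> None:
        """Require an entry for every interface class present in the tissue."""
        missing = set()
        for eid in tissue.edges:
            a, b = tissue.edge_regions()[eid]
            if b is None:
                continue
            ta, tb = tissue.region_type(a), tissue.region_type(b)
            if (ta, tb) not in self:
                missing.add(tuple(sorted((ta, tb))))
        if missing:
            raise KeyError(f"tension table is missing interface classes: "
                           f"{sorted(missing)}")

    def assign(self, tissue: Tissue) -> None:
        """Stamp every edge's tension from its current interface class."""
        self.validate_total(tissue)
        for e in tissue.edges.values():
            a, b = tissue.edge_regions()[e.id]
            e.tension = self.get(tissue.region_type(a), tissue.region_type(b))

    @classmethod
    def uniform(cls, gamma: float, types: Iterable[str],
                medium_label: str = MEDIUM) -> "TensionTable":
        t = cls()
        labels = list(types) + [medium_label]
        for i, a in enumerate(labels):
            for b in labels[i:]:
                t.set(a, b, gamma)
        return t

    def to_dict(self) -> Dict[str, float]:
        return {",".join(sorted(k)): v for k, v in self._map.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TensionTable":
        t = cls()
        for key, g in d.items():
            parts = [p.strip() for p in key.split(",")]
            if len(parts) == 1:
                parts = parts * 2
            t.set(parts[0], parts[1], g)
        return t
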
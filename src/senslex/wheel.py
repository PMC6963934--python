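"""Hierarchical sensory wheel: macro-category -> subcategory -> descriptor.

The wheel is the shared vocabulary for ultra-flash profiling. Assessors pick
descriptors from the outer ring; for the odor & aroma macro-category they may
instead cite one of its generic subcategories (vegetable, fruity, toasted,
spicy), which are flagged ``selectable``. The selectable set — outer-ring
descriptors plus selectable subcategories — is what the citation-probability
model counts; the bundled default wheel has 46 selectable attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .lexicon import RankedLexicon

__all__ = ["Subcategory", "SensoryWheel", "load_default_wheel", "build_wheel"]


@dataclass(frozen=True)
class Subcategory:
    name: str
    selectable: bool
    descriptors: tuple[str, ...]


@dataclass(frozen=True)
class SensoryWheel:
    """Validated three-level descriptor hierarchy."""

    name: str
    categories: tuple[tuple[str, tuple[Subcategory, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for macro, subs in self.categories:
            if not subs:
                raise ValueError(f"macro-category {macro!r} has no subcategories")
            for sub in subs:
                if not sub.descriptors:
                    raise ValueError(f"subcategory {sub.name!r} is empty")
                for d in sub.descriptors:
                    if d in seen:
                        raise ValueError(f"duplicate descriptor {d!r}")
                    seen.add(d)
        if not self.selectable_set():
            raise ValueError("wheel has an empty selectable set")

    def selectable_set(self) -> tuple[str, ...]:
        """Ordered selectable attributes: ring order within category order.

        Selectable subcategory names follow their own descriptors, so
        permuting the config's category order permutes the output the same
        way. Length is the model's ``d``.
        """
        out: list[str] = []
        for _, subs in self.categories:
            for sub in subs:
                out.extend(sub.descriptors)
                if sub.selectable:
                    out.append(sub.name)
        return tuple(out)

    @property
    def n_selectable(self) -> int:
        return len(self.selectable_set())

    def outer_ring(self) -> tuple[str, ...]:
        return tuple(d for _, subs in self.categories for s in subs for d in s.descriptors)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "categories": [
                {
                    "macro_category": macro,
                    "subcategories": [
                        {
                            "name": s.name,
                            "selectable": s.selectable,
                            "descriptors": list(s.descriptors),
                        }
                        for s in subs
                    ],
                }
                for macro, subs in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "SensoryWheel":
        cats = tuple(
            (
                c["macro_category"],
                tuple(
                    Subcategory(
                        name=s["name"],
                        selectable=bool(s.get("selectable", False)),
                        descriptors=tuple(s["descriptors"]),
                    )
                    for s in c["subcategories"]
                ),
            )
            for c in raw["categories"]
        )
        return cls(name=raw.get("name", "wheel"), categories=cats)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), "utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SensoryWheel":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SensoryWheel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text("utf-8")))

    def to_table(self) -> pd.DataFrame:
        """Plot-ready two-column view: hierarchy path, descriptor label."""
        rows = [
            (f"{macro}/{s.name}", d)
            for macro, subs in self.categories
            for s in subs
            for d in s.descriptors
        ]
        return pd.DataFrame(rows, columns=["path", "descriptor"])


def load_default_wheel() -> SensoryWheel:
    """The bundled 46-attribute apple-juice wheel (synthetic fixture)."""
    text = resources.files("senslex.data").joinpath("default_wheel.yaml").read_text("utf-8")
    return SensoryWheel.from_dict(yaml.safe_load(text))


def build_wheel(
    lexicon: RankedLexicon,
    hierarchy_config: dict,
    additions: set[str] | None = None,
) -> tuple[SensoryWheel, list[str]]:
    """Assemble a wheel from a mined lexicon plus an explicit hierarchy.

    Every descriptor in the config must resolve to a lexicon term or be
    declared in ``additions`` (terms introduced to complete the wheel beyond
    what the corpus yielded). Returns the validated wheel together with the
    list of unresolved descriptors; structural violations (duplicates, empty
    categories) raise.
    """
    additions = set(additions or hierarchy_config.get("additions", []))
    known = set(lexicon.terms) | additions
    wheel = SensoryWheel.from_dict(hierarchy_config)
    unresolved = [d for d in wheel.outer_ring() if d not in known]
    return wheel, unresolved
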
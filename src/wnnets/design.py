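"""Sample-to-group assignment and the list of treated-vs-control comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml


def comparison_label(treated: str, control: str) -> str:
    """Conventional label for a comparison, control first (e.g. ``NH-H``)."""
    return f"{control}-{treated}"


@dataclass(frozen=True)
class ComparisonDesign:
    """Group membership of samples plus the ordered (treated, control) pairs.

    ``groups`` maps a group label to the ordered list of sample ids in that
    group; every sample belongs to exactly one group.  ``comparisons`` lists
    the treated/control pairs that the differential statistics will test.
    """

    groups: Mapping[str, Sequence[str]]
    comparisons: Sequence[tuple[str, str]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, samples in self.groups.items():
            if len(samples) == 0:
                raise ValueError(f"group {group!r} has no samples")
            for s in samples:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {group!r}"
                    )
                seen[s] = group
        for treated, control in self.comparisons:
            if treated not in self.groups:
                raise ValueError(f"unknown treated group {treated!r}")
            if control not in self.groups:
                raise ValueError(f"unknown control group {control!r}")
            if treated == control:
                raise ValueError(f"comparison {treated!r} vs itself is not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return [s for samples in self.groups.values() for s in samples]

    def group_of(self, sample: str) -> str:
        for group, samples in self.groups.items():
            if sample in samples:
                return group
        raise KeyError(sample)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups[group])

    @classmethod
    def from_sample_map(
        cls,
        sample_to_group: Mapping[str, str],
        comparisons: Iterable[Sequence[str]] = (),
    ) -> "ComparisonDesign":
        groups: dict[str, list[str]] = {}
        for sample, group in sample_to_group.items():
            groups.setdefault(str(group), []).append(str(sample))
        pairs = tuple((str(t), str(c)) for t, c in comparisons)
        return cls(groups=groups, comparisons=pairs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComparisonDesign":
        """Read a design file: a ``samples: {id: group}`` mapping plus a
        ``comparisons`` list of ``[treated, control]`` pairs."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "samples" not in raw:
            raise ValueError(f"{path}: design file needs a 'samples' mapping")
        comparisons = raw.get("comparisons", [])
        for pair in comparisons:
            if len(pair) != 2:
                raise ValueError(f"{path}: comparison {pair!r} is not a pair")
        return cls.from_sample_map(raw["samples"], comparisons)

    def to_yaml(self, path: str | Path) -> None:
        sample_map = {s: g for g, samples in self.groups.items() for s in samples}
        payload = {
            "samples": sample_map,
            "comparisons": [list(pair) for pair in self.comparisons],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def four_group_design(
    n_per_group: int = 6,
    group_names: Sequence[str] = ("NH", "H", "NU", "U"),
    comparisons: Sequence[tuple[str, str]] = (("H", "NH"), ("U", "NU")),
) -> ComparisonDesign:
    """The study layout used throughout: 4 groups of 6 myocardial samples,
    each treated group compared against its paired healthy control."""
    groups = {
        g: [f"{g}_{i + 1}" for i in range(n_per_group)] for g in group_names
    }
    return ComparisonDesign(groups=groups, comparisons=tuple(comparisons))
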
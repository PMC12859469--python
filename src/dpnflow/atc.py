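"""ATC taxonomy: the 24 therapeutic classes used as network nodes.

Medications are grouped from their Anatomical Therapeutic Chemical (ATC)
code into 24 therapeutic classes by longest-prefix match against an
ordered rule table.  Every anatomical root (A, B, C, ...) maps to one
class, while the nervous-system root N is split into its therapeutic
subgroups (anesthetics N01, analgesics N02, ..., antidepressants N06A,
...), which is what puts antidepressants and anxiolytics on separate
network nodes.

The default rule table ships as a packaged CSV
(``dpnflow/data/atc_classes.csv``) so the grouping is inspectable and
replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AtcClassMap",
    "UnmappedAtcError",
    "default_class_map",
    "map_atc_to_class",
    "is_valid_atc",
    "N_CLASSES",
]

#: Number of therapeutic classes (network nodes).
N_CLASSES = 24

# ATC syntax: root letter + 2 digits, then optional level-3 letter,
# level-4 letter, level-5 two digits.
_ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")

#: Index classes defining the study cohort.
ANTIDEPRESSANTS = "Antidepressants"
ANXIOLYTICS = "Anxiolytics"


class UnmappedAtcError(KeyError):
    """Raised when an ATC code matches no rule in the class map."""


def is_valid_atc(code: str) -> bool:
    """Check ATC syntax (root letter, 2 digits, optional deeper levels)."""
    return bool(_ATC_RE.match(code))


@dataclass(frozen=True)
class AtcClassMap:
    """Ordered (atc_prefix, class_label) rules with longest-prefix-match.

    Attributes
    ----------
    rules
        Ordered ``(prefix, label)`` pairs.  When several prefixes match a
        code, the longest one wins; rule order only breaks exact-length
        ties (first wins), which a well-formed table never needs.
    class_labels
        The distinct labels in first-appearance order; their position is
        the node index used by every adjacency matrix downstream.
    """

    rules: tuple[tuple[str, str], ...]
    class_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for _, label in self.rules:
            if label not in seen:
                seen.append(label)
        object.__setattr__(self, "class_labels", tuple(seen))

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_index(self, label: str) -> int:
        return self.class_labels.index(label)

    def map_code(self, atc_code: str) -> str:
        """Map one ATC code to its class label (longest matching prefix)."""
        if not is_valid_atc(atc_code):
            raise ValueError(f"syntactically invalid ATC code: {atc_code!r}")
        best: str | None = None
        best_len = -1
        for prefix, label in self.rules:
            if atc_code.startswith(prefix) and len(prefix) > best_len:
                best, best_len = label, len(prefix)
        if best is None:
            raise UnmappedAtcError(f"ATC code {atc_code!r} matches no rule in the class map")
        return best

    def map_series(self, codes: pd.Series) -> pd.Series:
        """Vectorised :meth:`map_code` over a pandas Series (same errors)."""
        unique = pd.unique(codes)
        lookup = {c: self.map_code(c) for c in unique}
        return codes.map(lookup)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtcClassMap":
        df = pd.read_csv(path, dtype=str)
        missing = {"atc_prefix", "class_label"} - set(df.columns)
        if missing:
            raise ValueError(f"class map file missing columns: {sorted(missing)}")
        return cls(tuple(zip(df["atc_prefix"], df["class_label"])))


def default_class_map() -> AtcClassMap:
    """The packaged 24-class grouping."""
    with resources.as_file(
        resources.files("dpnflow.data").joinpath("atc_classes.csv")
    ) as p:
        cmap = AtcClassMap.from_csv(p)
    if cmap.n_classes != N_CLASSES:  # pragma: no cover - packaging guard
        raise RuntimeError(
            f"packaged class map defines {cmap.n_classes} classes, expected {N_CLASSES}"
        )
    return cmap


def map_atc_to_class(atc_code: str, class_map: AtcClassMap | None = None) -> str:
    """Map an ATC code to one of the 24 therapeutic class labels."""
    cmap = class_map if class_map is not None else default_class_map()
    return cmap.map_code(atc_code)
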
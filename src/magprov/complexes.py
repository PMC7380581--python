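"""Presence/absence calling of multi-subunit complexes from annotations.

A complex is called present in a bin when at least a threshold fraction of
its subunit genes are detected in the annotation table (default 75%,
inclusive, so 6 of 8 MTR subunits is enough). Matching is case-insensitive
on gene label or KO id, after resolving a synonym map; each subunit counts
at most once regardless of paralog copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .io import Feature

CATEGORIES = {
    "nitrate", "sulfate", "iron", "methanogenesis", "beta_oxidation",
    "biosynthesis", "other",
}

DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class ComplexDef:
    """Definition of one functional complex (or single-gene marker)."""

    name: str
    subunits: frozenset[str]
    category: str = "other"
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError(f"complex {self.name!r} has an empty subunit set")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"complex {self.name!r}: threshold must be in (0, 1]")
        if self.category not in CATEGORIES:
            raise ValueError(f"complex {self.name!r}: unknown category {self.category!r}")


@dataclass
class PresenceCall:
    """Outcome of calling one complex in one bin."""

    bin_id: str
    complex_name: str
    detected: frozenset[str]
    n_subunits: int
    present: bool

    @property
    def fraction(self) -> float:
        return len(self.detected) / self.n_subunits


def load_catalog(path: Optional[str | Path] = None) -> tuple[list[ComplexDef], dict[str, str]]:
    """Load a YAML complex catalog; default is the shipped one.

    Returns the complex definitions (in file order) and the synonym map.
    """
    if path is None:
        text = resources.files("magprov.data").joinpath("complexes.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    synonyms = {k.lower(): v.lower() for k, v in (doc.get("synonyms") or {}).items()}
    defs = []
    for entry in doc["complexes"]:
        subunits = frozenset(s.lower() for s in entry["subunits"])
        threshold = entry.get(
            "threshold", 1.0 if len(subunits) == 1 else DEFAULT_THRESHOLD
        )
        defs.append(
            ComplexDef(
                name=entry["name"],
                subunits=subunits,
                category=entry.get("category", "other"),
                threshold=float(threshold),
            )
        )
    return defs, synonyms


def _resolve(label: str, synonyms: Mapping[str, str]) -> str:
    label = label.lower()
    return synonyms.get(label, label)


def call_complex(
    features: Iterable[Feature],
    cdef: ComplexDef,
    synonyms: Optional[Mapping[str, str]] = None,
    bin_id: str = "",
) -> PresenceCall:
    """Call one complex from one bin's features (inclusive >= threshold rule)."""
    synonyms = synonyms or {}
    labels = set()
    for f in features:
        if f.gene_label:
            labels.add(_resolve(f.gene_label, synonyms))
        if f.ko_id:
            labels.add(f.ko_id.lower())
    detected = frozenset(s for s in cdef.subunits if s in labels)
    # exact rational comparison: 6/8 against 0.75 must not suffer float fuzz
    present = Fraction(len(detected), len(cdef.subunits)) >= Fraction(cdef.threshold)
    return PresenceCall(
        bin_id=bin_id,
        complex_name=cdef.name,
        detected=detected,
        n_subunits=len(cdef.subunits),
        present=present,
    )


def presence_matrix(
    bin_features: Mapping[str, Iterable[Feature]],
    defs: Iterable[ComplexDef],
    synonyms: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Bin x complex boolean matrix of presence calls.

    Columns follow the catalog order (which encodes the category order of
    the shipped config); rows follow the bin mapping order.
    """
    defs = list(defs)
    if not defs:
        raise ValueError("no complex definitions supplied")
    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate complex names: {dupes}")
    if not bin_features:
        raise ValueError("no bins supplied")
    rows = {}
    for bin_id, feats in bin_features.items():
        feats = list(feats)
        rows[bin_id] = {
            d.name: call_complex(feats, d, synonyms, bin_id).present for d in defs
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def presence_calls(
    bin_features: Mapping[str, Iterable[Feature]],
    defs: Iterable[ComplexDef],
    synonyms: Optional[Mapping[str, str]] = None,
) -> list[PresenceCall]:
    """Flat list of all calls behind :func:`presence_matrix`."""
    calls = []
    for bin_id, feats in bin_features.items():
        feats = list(feats)
        for d in defs:
            calls.append(call_complex(feats, d, synonyms, bin_id))
    return calls


def plot_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the presence matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(2, 0.4 * matrix.shape[0]))
    )
    ax.imshow(matrix.to_numpy(dtype=float), cmap="Blues", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
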
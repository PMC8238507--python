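"""64-channel 10-10 electrode layout and the derived bipolar montage.

The montage ships as versioned packaged data rather than being re-derived
geometrically at run time: ``electrodes_1010.tsv`` holds the 64 scalp
positions (azimuthal equidistant projection, unit square), and
``bipolar_pairs.tsv`` holds the 112 neighbor pairs together with the nine
occipito-parietal pairs used for band-power analysis, split into their
three groups (left / right / midline-occipital).

Pairing scheme (documented, not inherited from any single reference):
within-row adjacent electrodes — excluding pairs that straddle a 10-10
midline grid site absent from this cap (Fpz, AFz, FCz) — plus same-column
pairs between adjacent coronal rows, plus nearest-diagonal pairs where an
electrode has no same-column partner. Pair names follow the convention
"anode-cathode" with the anode the more posterior (between rows) or more
medial (within a row) electrode; the bipolar signal is anode minus cathode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "BipolarMontage",
    "build_layout",
    "derive_bipolar",
    "propagate_bad",
    "apply_bipolar",
    "ANALYSIS_PAIRS",
]

#: The nine analysis pairs, grouped as printed: left, right, midline-occipital.
ANALYSIS_GROUPS: Dict[str, Tuple[str, ...]] = {
    "g1": ("PO3-P1", "PO3-P3", "POz-PO3"),
    "g2": ("PO4-P2", "PO4-P4", "POz-PO4"),
    "g3": ("Oz-POz", "Oz-O1", "Oz-O2"),
}
ANALYSIS_PAIRS: Tuple[str, ...] = sum(ANALYSIS_GROUPS.values(), ())


class MontageError(ValueError):
    """Configuration error in layout or montage data."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """64 uniquely named 10-10 electrodes with 2D scalp coordinates."""

    entries: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.entries) != 64:
            raise MontageError(f"expected 64 electrodes, got {len(self.entries)}")
        for name, (x, y) in self.entries.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise MontageError(f"non-finite coordinate for {name}")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class BipolarMontage:
    """112 ordered (anode, cathode) pairs plus the 9-pair analysis set."""

    pairs: Tuple[Tuple[str, str, str], ...]  # (pair_name, anode, cathode)
    analysis_groups: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(ANALYSIS_GROUPS)
    )

    def __post_init__(self) -> None:
        names = [p[0] for p in self.pairs]
        if len(set(names)) != len(names):
            raise MontageError("duplicate pair names")
        members = {frozenset((a, c)) for _, a, c in self.pairs}
        if len(members) != len(self.pairs):
            raise MontageError("duplicate electrode pairs")
        missing = set(self.analysis_set) - set(names)
        if missing:
            raise MontageError(f"analysis pairs missing from montage: {sorted(missing)}")

    @property
    def pair_names(self) -> Tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def analysis_set(self) -> Tuple[str, ...]:
        return sum(self.analysis_groups.values(), ())

    def electrodes_of(self, pair_name: str) -> Tuple[str, str]:
        for name, a, c in self.pairs:
            if name == pair_name:
                return a, c
        raise MontageError(f"unknown pair {pair_name!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def _data_lines(fname: str) -> List[List[str]]:
    text = resources.files("gammacc.data").joinpath(fname).read_text()
    rows = [line.split("\t") for line in text.strip().splitlines()]
    return rows[1:]  # drop header


def build_layout() -> ElectrodeLayout:
    """Load the packaged 64-electrode 10-10 layout. Deterministic."""
    entries = {name: (float(x), float(y)) for name, x, y in _data_lines("electrodes_1010.tsv")}
    return ElectrodeLayout(entries=entries)


def derive_bipolar(layout: ElectrodeLayout) -> BipolarMontage:
    """Derive the neighbor-pair bipolar montage for ``layout``.

    Returns the packaged 112-pair list after validating every member
    against the layout. Raises :class:`MontageError` if an electrode named
    in the pair table is not present.
    """
    pairs = []
    for pair_name, anode, cathode, _group in _data_lines("bipolar_pairs.tsv"):
        for e in (anode, cathode):
            if e not in layout:
                raise MontageError(f"pair {pair_name} references unknown electrode {e!r}")
        pairs.append((pair_name, anode, cathode))
    return BipolarMontage(pairs=tuple(pairs))


def propagate_bad(montage: BipolarMontage, bad_unipolars: Iterable[str]) -> Set[str]:
    """Bad bipolar pairs: those with either constituent electrode bad."""
    bad = set(bad_unipolars)
    known = {e for _, a, c in montage.pairs for e in (a, c)}
    unknown = bad - known
    if unknown:
        raise MontageError(f"unknown electrode names: {sorted(unknown)}")
    return {name for name, a, c in montage.pairs if a in bad or c in bad}


def apply_bipolar(
    data: np.ndarray,
    channel_names: Sequence[str],
    montage: BipolarMontage,
    pair_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Re-reference unipolar data to bipolar pairs (anode minus cathode).

    Parameters
    ----------
    data
        Array with channels on axis -2 and samples on axis -1.
    channel_names
        Unipolar channel names matching axis -2 of ``data``.
    pair_names
        Pairs to derive; defaults to the montage's analysis set.
    """
    if pair_names is None:
        pair_names = montage.analysis_set
    idx = {name: i for i, name in enumerate(channel_names)}
    out = []
    for pn in pair_names:
        a, c = montage.electrodes_of(pn)
        if a not in idx or c not in idx:
            raise MontageError(f"pair {pn} needs channels {a},{c} not in data")
        out.append(data[..., idx[a], :] - data[..., idx[c], :])
    return np.stack(out, axis=-2)
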
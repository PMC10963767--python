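"""Body-map location vocabulary and one-hot encoding.

A body map is a numbered atlas of anatomical regions; each wound is
tagged with one integer region ID in 1..484. The canonical atlas used in
chronic-wound documentation has 484 regions, but only example names are
public (e.g. 135 = "Right fifth toe tip", 150 = "Right lateral heel"), so
:func:`canonical_bodymap` ships IDs 1..484 with the known example names
filled in and neutral placeholders elsewhere. All downstream logic
depends only on the IDs and the vocabulary size, never on names.

The one-hot position of an ID is its rank in ascending ID order, so
sparse or custom vocabularies encode without gaps.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

CANONICAL_SIZE = 484

#: Example region names that are publicly documented (lower-leg atlas excerpt).
KNOWN_REGION_NAMES: dict[int, str] = {
    135: "Right fifth toe tip",
    150: "Right lateral heel",
    158: "Right medial malleolus",
    159: "Right proximal lateral dorsal foot",
    178: "Left medial malleolus",
    180: "Left anterior ankle",
    202: "Left fifth toe tip",
    215: "Left proximal medial plantar foot",
}


class BodyMapError(ValueError):
    """Raised for malformed vocabularies or unregistered location IDs."""


@dataclass(frozen=True)
class BodyMapEntry:
    location_id: int
    name: str

    def __post_init__(self):
        if not 1 <= self.location_id <= CANONICAL_SIZE:
            raise BodyMapError(
                f"location_id {self.location_id} outside the body-map range 1..{CANONICAL_SIZE}"
            )


class BodyMap:
    """An ordered region vocabulary with total, loud-failing ID lookup."""

    def __init__(self, entries: list[BodyMapEntry]):
        ids = [e.location_id for e in entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise BodyMapError(f"duplicate location_id(s): {sorted(dupes)}")
        self._entries = sorted(entries, key=lambda e: e.location_id)
        self._pos = {e.location_id: i for i, e in enumerate(self._entries)}

    @property
    def size(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[BodyMapEntry]:
        return list(self._entries)

    @property
    def ids(self) -> list[int]:
        return [e.location_id for e in self._entries]

    def __contains__(self, location_id: int) -> bool:
        return location_id in self._pos

    def lookup(self, location_id: int) -> str:
        """Anatomical name for a registered ID; raises for anything else."""
        try:
            return self._entries[self._pos[location_id]].name
        except KeyError:
            raise BodyMapError(f"location_id {location_id} not registered in this body map") from None

    def position(self, location_id: int) -> int:
        """One-hot index of an ID: its rank in ascending ID order."""
        try:
            return self._pos[location_id]
        except KeyError:
            raise BodyMapError(f"location_id {location_id} not registered in this body map") from None

    def id_at(self, position: int) -> int:
        return self._entries[position].location_id


def canonical_bodymap() -> BodyMap:
    """The shipped 484-region atlas (known example names, placeholders elsewhere)."""
    entries = [
        BodyMapEntry(i, KNOWN_REGION_NAMES.get(i, f"Region {i}"))
        for i in range(1, CANONICAL_SIZE + 1)
    ]
    return BodyMap(entries)


def load_bodymap(source: str | Path) -> BodyMap:
    """Load a vocabulary table from CSV (``location_id,name``) or JSON ``{id: name}``.

    Raises
    ------
    BodyMapError
        On duplicate IDs (naming the ID) or a malformed row (naming the line).
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[BodyMapEntry] = []
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        for key, name in mapping.items():
            try:
                lid = int(key)
            except ValueError:
                raise BodyMapError(f"non-integer location_id {key!r} in {path}") from None
            entries.append(BodyMapEntry(lid, str(name)))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["location_id", "name"]:
                raise BodyMapError(f"{path}: expected header 'location_id,name'")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 2:
                    raise BodyMapError(f"{path}:{lineno}: malformed row {row!r}")
                try:
                    lid = int(row[0])
                except ValueError:
                    raise BodyMapError(f"{path}:{lineno}: non-integer location_id {row[0]!r}") from None
                entries.append(BodyMapEntry(lid, row[1].strip()))
    return BodyMap(entries)


def write_bodymap(bmap: BodyMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["location_id", "name"])
        for e in bmap.entries:
            writer.writerow([e.location_id, e.name])


def encode_location(bmap: BodyMap, location_id: int) -> np.ndarray:
    """One-hot encode a registered location ID (vector length = map size)."""
    vec = np.zeros(bmap.size)
    vec[bmap.position(location_id)] = 1.0
    return vec


def decode_location(bmap: BodyMap, vector: np.ndarray) -> int:
    """Inverse of :func:`encode_location` (argmax position -> ID)."""
    vector = np.asarray(vector)
    if vector.shape != (bmap.size,):
        raise BodyMapError(f"expected vector of length {bmap.size}, got shape {vector.shape}")
    return bmap.id_at(int(np.argmax(vector)))


def align_locations(manifest, bmap: BodyMap) -> list[np.ndarray]:
    """One-hot encodings for every record, in manifest order.

    Index-based synchronization: record *i*'s encoding sits at position
    *i*, so image and location streams stay aligned downstream.

    Raises
    ------
    BodyMapError
        If a record has no location (the location branch needs one) or an
        unregistered ID (a manifest/body-map mismatch).
    """
    encodings: list[np.ndarray] = []
    for i, rec in enumerate(manifest.records):
        if rec.location_id is None:
            raise BodyMapError(
                f"record {i} ({rec.image_ref}) has no location_id but the location branch is enabled"
            )
        encodings.append(encode_location(bmap, rec.location_id))
    return encodings
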
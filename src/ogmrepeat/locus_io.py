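"""Locus definition, Bionano CMAP/XMAP parsing, and intermarker distance extraction.

The native currency of the downstream algorithm is a per-sample list of
per-molecule intermarker distances in bp (:class:`DistanceSet`).  This module
produces such sets either by parsing molecule-to-reference alignments (XMAP)
together with the reference and query label maps (CMAP), or by reading the
canonical tab-separated distance table.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    ConsistencyError,
    EmptyInputError,
    FormatError,
    LocusResolutionError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Maximum distance (bp) allowed when resolving a genomic marker position to
#: the nearest reference label site.
MARKER_RESOLUTION_TOLERANCE_BP = 500.0

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")
_ALIGNMENT_RE = re.compile(r"^(?:\(\d+,\d+\))+$")
_PAIR_RE = re.compile(r"\((\d+),(\d+)\)")


@dataclass(frozen=True)
class LocusSpec:
    """A repeat locus defined by its two flanking label sites.

    The reference intermarker distance is the span between the flanking
    markers on the reference; the expansion size of a molecule is its own
    intermarker distance minus this reference distance.
    """

    chrom: str
    marker_left_pos: int
    marker_right_pos: int
    motif_length_bp: int = 5
    marker_left_id: int | None = None
    marker_right_id: int | None = None

    def __post_init__(self) -> None:
        if self.marker_right_pos <= self.marker_left_pos:
            raise ValidationError(
                f"marker_right_pos ({self.marker_right_pos}) must exceed "
                f"marker_left_pos ({self.marker_left_pos})"
            )
        if self.motif_length_bp < 1:
            raise ValidationError("motif_length_bp must be >= 1")

    @property
    def reference_distance_bp(self) -> int:
        return self.marker_right_pos - self.marker_left_pos

    @classmethod
    def from_region(
        cls,
        region: str,
        motif_length_bp: int = 5,
        marker_left_id: int | None = None,
        marker_right_id: int | None = None,
    ) -> "LocusSpec":
        """Build a locus from a ``chrom:start-end`` region string."""
        m = _REGION_RE.match(region.strip())
        if m is None:
            raise ValidationError(f"cannot parse locus region {region!r}; expected chrom:start-end")
        return cls(
            chrom=m.group("chrom"),
            marker_left_pos=int(m.group("start")),
            marker_right_pos=int(m.group("end")),
            motif_length_bp=motif_length_bp,
            marker_left_id=marker_left_id,
            marker_right_id=marker_right_id,
        )


#: The RFC1 AAGGG-type pentanucleotide locus on hg38, flanked by reference
#: label sites 7723 and 7724 (span 6858 bp).
RFC1_LOCUS = LocusSpec(
    chrom="chr4",
    marker_left_pos=39343732,
    marker_right_pos=39350590,
    motif_length_bp=5,
    marker_left_id=7723,
    marker_right_id=7724,
)


@dataclass
class LabelMap:
    """An ordered set of label sites on one map (reference contig or molecule)."""

    map_id: int
    positions: list[tuple[int, float]]
    length_bp: float

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.positions]
        pos = [p for _, p in self.positions]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError(f"map {self.map_id}: site ids must be strictly increasing")
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValidationError(f"map {self.map_id}: positions must be non-decreasing")
        if any(p > self.length_bp for p in pos):
            raise ValidationError(f"map {self.map_id}: position beyond map length")

    def position_of(self, site_id: int) -> float:
        for sid, pos in self.positions:
            if sid == site_id:
                return pos
        raise KeyError(f"site {site_id} not on map {self.map_id}")

    def site_ids(self) -> list[int]:
        return [s for s, _ in self.positions]


@dataclass
class MoleculeAlignment:
    """One molecule-to-reference alignment (one XMAP row)."""

    molecule_id: int
    ref_contig_id: int
    orientation: str
    pairs: list[tuple[int, int]]
    confidence: float

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError(f"alignment of molecule {self.molecule_id} has no matched pairs")
        refs = [r for r, _ in self.pairs]
        if any(b < a for a, b in zip(refs, refs[1:])):
            raise ValidationError(
                f"alignment of molecule {self.molecule_id}: ref site ids must be non-decreasing"
            )

    def query_sites_for(self, ref_site_id: int) -> list[int]:
        return [q for r, q in self.pairs if r == ref_site_id]


@dataclass
class DistanceSet:
    """Per-sample intermarker distances, one per molecule spanning both markers."""

    sample_id: str
    distances_bp: list[float] = field(default_factory=list)
    molecule_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.distances_bp) != len(self.molecule_ids):
            raise ValidationError("distances_bp and molecule_ids must be parallel")
        if any(d <= 0 for d in self.distances_bp):
            raise ValidationError("all distances must be > 0")

    def __len__(self) -> int:
        return len(self.distances_bp)


def _read_bionano_table(path: str, required: Sequence[str], what: str) -> list[dict[str, str]]:
    """Read a '#'-headed Bionano tab-separated file into row dicts.

    Columns are located by name from the last ``#h`` header line; unknown
    columns are carried along untouched.
    """
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#h"):
                    header = line[2:].strip().split("\t")
                    if len(header) == 1:  # some writers use spaces after '#h'
                        header = line[2:].split()
                continue
            fields = line.split("\t")
            if header is None:
                raise FormatError(f"{what} {path}: data row before '#h' header line")
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise EmptyInputError(f"{what} {path}: no '#h' header line found")
    for col in required:
        if col not in header:
            raise FormatError(f"{what} {path}: missing required column {col!r}")
    if not rows:
        raise EmptyInputError(f"{what} {path}: no data rows")
    return rows


def read_cmap(path: str) -> list[LabelMap]:
    """Parse a CMAP file into one :class:`LabelMap` per CMapId.

    Channel-end sentinel rows (``LabelChannel`` 0) carry the map end, not a
    label, and are excluded from the site list.
    """
    rows = _read_bionano_table(path, ["CMapId", "ContigLength", "SiteID", "Position"], "CMAP")
    by_map: dict[int, list[tuple[int, float]]] = {}
    lengths: dict[int, float] = {}
    for i, row in enumerate(rows, start=1):
        try:
            map_id = int(row["CMapId"])
            site_id = int(row["SiteID"])
            position = float(row["Position"])
            length = float(row["ContigLength"])
        except ValueError as exc:
            raise ParseError(f"CMAP {path}: unparseable field in data row {i}: {exc}") from exc
        lengths[map_id] = length
        if row.get("LabelChannel", "1") == "0":
            continue
        by_map.setdefault(map_id, []).append((site_id, position))
    maps = []
    for map_id in sorted(by_map):
        sites = sorted(by_map[map_id])
        maps.append(LabelMap(map_id=map_id, positions=sites, length_bp=lengths[map_id]))
    return maps


def parse_alignment_string(text: str, entry_id: str = "?") -> list[tuple[int, int]]:
    """Parse an XMAP ``Alignment`` column value into (ref, qry) site-id pairs."""
    text = text.strip()
    if not _ALIGNMENT_RE.match(text):
        raise ParseError(f"XMAP entry {entry_id}: malformed Alignment string {text!r}")
    return [(int(r), int(q)) for r, q in _PAIR_RE.findall(text)]


def read_xmap(path: str) -> list[MoleculeAlignment]:
    """Parse an XMAP file into a list of :class:`MoleculeAlignment`."""
    required = ["XmapEntryID", "QryContigID", "RefContigID", "Orientation", "Confidence", "Alignment"]
    rows = _read_bionano_table(path, required, "XMAP")
    alignments = []
    for row in rows:
        entry_id = row["XmapEntryID"]
        pairs = parse_alignment_string(row["Alignment"], entry_id=entry_id)
        orientation = row["Orientation"]
        if orientation not in {"+", "-", "−"}:
            raise ParseError(f"XMAP entry {entry_id}: invalid orientation {orientation!r}")
        alignments.append(
            MoleculeAlignment(
                molecule_id=int(row["QryContigID"]),
                ref_contig_id=int(row["RefContigID"]),
                orientation="-" if orientation != "+" else "+",
                pairs=pairs,
                confidence=float(row["Confidence"]),
            )
        )
    return alignments


def resolve_marker_sites(ref_map: LabelMap, locus: LocusSpec) -> tuple[int, int]:
    """Resolve the locus' flanking markers to reference label site ids.

    Explicit marker ids win when they exist on the reference map; otherwise
    each marker position is matched to the nearest reference label within
    ``MARKER_RESOLUTION_TOLERANCE_BP``.
    """
    ids = set(ref_map.site_ids())
    if (
        locus.marker_left_id is not None
        and locus.marker_right_id is not None
        and locus.marker_left_id in ids
        and locus.marker_right_id in ids
    ):
        return locus.marker_left_id, locus.marker_right_id

    def nearest(target: float) -> int:
        best_site, best_d = None, None
        for sid, pos in ref_map.positions:
            d = abs(pos - target)
            if best_d is None or d < best_d:
                best_site, best_d = sid, d
        if best_site is None or best_d > MARKER_RESOLUTION_TOLERANCE_BP:
            raise LocusResolutionError(
                f"no reference label within {MARKER_RESOLUTION_TOLERANCE_BP:.0f} bp "
                f"of position {target}"
            )
        return best_site

    return nearest(locus.marker_left_pos), nearest(locus.marker_right_pos)


def extract_intermarker_distances(
    alignments: Iterable[MoleculeAlignment],
    ref_map: LabelMap,
    qry_maps: Iterable[LabelMap],
    locus: LocusSpec,
    sample_id: str,
) -> DistanceSet:
    """Collect intermarker distances over all molecules overlapping both markers.

    For each alignment matching BOTH flanking reference sites, the distance is
    the absolute difference of the matched query-label positions on the
    molecule's own label map (orientation-independent).  Molecules missing
    either marker are skipped.  A reference marker matched by several query
    sites (split match) contributes the mean of the matched positions.
    """
    left_site, right_site = resolve_marker_sites(ref_map, locus)
    qry_by_id = {m.map_id: m for m in qry_maps}
    distances: list[float] = []
    molecule_ids: list[int] = []
    for aln in alignments:
        left_q = aln.query_sites_for(left_site)
        right_q = aln.query_sites_for(right_site)
        if not left_q or not right_q:
            continue
        qmap = qry_by_id.get(aln.molecule_id)
        if qmap is None:
            raise ConsistencyError(f"molecule {aln.molecule_id} aligned but absent from query maps")
        if len(left_q) > 1 or len(right_q) > 1:
            logger.info(
                "molecule %s: split marker match (left=%s right=%s); using mean positions",
                aln.molecule_id, left_q, right_q,
            )
        pos_left = sum(qmap.position_of(q) for q in left_q) / len(left_q)
        pos_right = sum(qmap.position_of(q) for q in right_q) / len(right_q)
        distance = abs(pos_right - pos_left)
        if distance <= 0:
            logger.warning("molecule %s: non-positive intermarker distance; skipped", aln.molecule_id)
            continue
        distances.append(distance)
        molecule_ids.append(aln.molecule_id)
    if not distances:
        logger.warning("sample %s: no molecules span both markers", sample_id)
    return DistanceSet(sample_id=sample_id, distances_bp=distances, molecule_ids=molecule_ids)


def write_distance_table(sets: Iterable[DistanceSet], path: str) -> None:
    """Write DistanceSets to the canonical TSV (3 decimal places)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "molecule_id", "distance_bp"])
        for dset in sets:
            for mol_id, dist in zip(dset.molecule_ids, dset.distances_bp):
                writer.writerow([dset.sample_id, mol_id, f"{dist:.3f}"])


def read_distance_table(path: str) -> list[DistanceSet]:
    """Read the canonical distance TSV, grouped by sample_id in file order."""
    order: list[str] = []
    grouped: dict[str, tuple[list[float], list[int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise EmptyInputError(f"{path}: empty file")
        expected = ["sample_id", "molecule_id", "distance_bp"]
        if [h.strip() for h in header] != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header}")
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            sample_id, mol_str, dist_str = row
            try:
                mol_id = int(mol_str)
                dist = float(dist_str)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if dist <= 0:
                raise ValidationError(f"{path}:{lineno}: distance_bp must be > 0, got {dist}")
            if sample_id not in grouped:
                order.append(sample_id)
                grouped[sample_id] = ([], [])
            grouped[sample_id][0].append(dist)
            grouped[sample_id][1].append(mol_id)
            n_rows += 1
        if n_rows == 0:
            raise EmptyInputError(f"{path}: no data rows")
    return [
        DistanceSet(sample_id=s, distances_bp=grouped[s][0], molecule_ids=grouped[s][1])
        for s in order
    ]
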
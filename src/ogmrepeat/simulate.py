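"""Synthetic molecule distance sets, alignment fixtures, and cohort tables.

The generator mirrors the data-generating assumptions of the sizing
algorithm: per-allele Gaussian dispersion (default SD 5% of the repeat
count), optional uniform outlier contamination, and an affine bias model
linking the simulated gel-based calls to the true sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .concordance import CohortRecord
from .errors import ValidationError
from .locus_io import RFC1_LOCUS, DistanceSet, LabelMap, LocusSpec, MoleculeAlignment
from .sizing import repeats_to_bp

DEFAULT_SD_FRACTION = 0.05
DEFAULT_SD_FLOOR_REPEATS = 10.0


@dataclass(frozen=True)
class AlleleSpec:
    """One true allele: repeat count, dispersion, mixture fraction."""

    repeats: float
    sd_repeats: float | None = None
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValidationError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.sd_repeats is not None and self.sd_repeats <= 0:
            raise ValidationError("sd_repeats must be > 0")

    @property
    def effective_sd_repeats(self) -> float:
        if self.sd_repeats is not None:
            return self.sd_repeats
        return max(DEFAULT_SD_FRACTION * abs(self.repeats), DEFAULT_SD_FLOOR_REPEATS)


@dataclass(frozen=True)
class SimConfig:
    n_molecules: int
    seed: int
    outlier_rate: float = 0.02
    outlier_range_bp: tuple[float, float] = (500.0, 60000.0)
    locus: LocusSpec = field(default_factory=lambda: RFC1_LOCUS)

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be positive")
        if not 0 <= self.outlier_rate < 1:
            raise ValidationError("outlier_rate must be in [0, 1)")
        lo, hi = self.outlier_range_bp
        if not 0 < lo < hi:
            raise ValidationError("outlier_range_bp must satisfy 0 < low < high")


@dataclass
class SimTruth:
    """Generating parameters recorded alongside a simulated sample."""

    alleles: list[AlleleSpec]
    config: SimConfig
    allele_assignments: list[int]
    outlier_indices: list[int]

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)


def simulate_molecule_distances(
    alleles: Sequence[AlleleSpec],
    config: SimConfig,
    sample_id: str = "sim",
) -> tuple[DistanceSet, SimTruth]:
    """Draw per-molecule intermarker distances from a 1-2 allele mixture.

    Each molecule picks an allele by fraction, then a distance from
    Normal(reference + repeats*motif, (sd_repeats*motif)^2); a
    Bernoulli(outlier_rate) subset is replaced by Uniform(outlier_range_bp).
    Deterministic under the config seed.
    """
    if not 1 <= len(alleles) <= 2:
        raise ValidationError("need 1 or 2 alleles")
    fractions = np.array([a.fraction for a in alleles], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError(f"allele fractions must sum to 1, got {fractions.sum()}")
    locus = config.locus
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    assign = rng.choice(len(alleles), size=n, p=fractions)
    means = np.array([repeats_to_bp(a.repeats, locus) for a in alleles])
    sds = np.array([a.effective_sd_repeats * locus.motif_length_bp for a in alleles])
    distances = rng.normal(means[assign], sds[assign])
    outlier_mask = rng.random(n) < config.outlier_rate
    lo, hi = config.outlier_range_bp
    distances[outlier_mask] = rng.uniform(lo, hi, size=int(outlier_mask.sum()))
    distances = np.maximum(distances, 1.0)  # distances are physical lengths
    dset = DistanceSet(
        sample_id=sample_id,
        distances_bp=[float(d) for d in distances],
        molecule_ids=list(range(1, n + 1)),
    )
    truth = SimTruth(
        alleles=list(alleles),
        config=config,
        allele_assignments=[int(a) for a in assign],
        outlier_indices=[int(i) for i in np.flatnonzero(outlier_mask)],
    )
    return dset, truth


def simulate_cohort(
    n_patients: int,
    allele_size_sampler: Callable[[np.random.Generator], float],
    sb_bias: tuple[float, float, float],
    lr_reads_per_patient: int,
    seed: int,
    ogm_sd_fraction: float = DEFAULT_SD_FRACTION,
    lr_noise_sd: float = 20.0,
) -> tuple[list[CohortRecord], dict[str, list[float]], list[dict]]:
    """Generate a synthetic cohort linking true sizes to SB/OGM/LR calls.

    Per patient, two true allele sizes come from the sampler.  OGM calls are
    truth + Normal(0, ogm_sd_fraction * truth); gel (SB) calls follow the
    affine bias SB = (truth - b)/a + Normal(0, noise_sd), so regressing OGM
    on SB recovers slope ~ a and intercept ~ b; LR reads are truth plus
    Normal noise.  Returns (records, lr_reads, truth rows).
    """
    a, b, noise_sd = sb_bias
    if a <= 0:
        raise ValidationError("sb bias slope a must be > 0")
    if noise_sd < 0 or lr_reads_per_patient < 0 or n_patients < 1:
        raise ValidationError("invalid cohort parameters")
    rng = np.random.default_rng(seed)
    records, lr_reads, truth_rows = [], {}, []
    for i in range(1, n_patients + 1):
        pid = f"SIM{i:03d}"
        true_sizes = sorted(float(allele_size_sampler(rng)) for _ in range(2))
        ogm = []
        sb = []
        for t in true_sizes:
            ogm_mean = t + rng.normal(0.0, max(ogm_sd_fraction * abs(t), 1e-9))
            ogm.append((ogm_mean, ogm_sd_fraction * abs(t)))
            sb.append((t - b) / a + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        reads = [
            float(np.mean(true_sizes) + (rng.normal(0.0, lr_noise_sd) if lr_noise_sd > 0 else 0.0))
            for _ in range(lr_reads_per_patient)
        ]
        records.append(
            CohortRecord(
                patient_id=pid,
                sb_alleles=tuple(sorted(sb)),
                ogm_alleles=tuple(sorted(ogm)),
            )
        )
        if reads:
            lr_reads[pid] = reads
        truth_rows.append({"patient_id": pid, "true_allele1": true_sizes[0], "true_allele2": true_sizes[1]})
    return records, lr_reads, truth_rows


# ---------------------------------------------------------------------------
# XMAP/CMAP fixture writer
# ---------------------------------------------------------------------------

_CMAP_HEADER = (
    "# CMAP File Version:\t0.2\n"
    "# Label Channels:\t1\n"
    "#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tStdDev\tCoverage\tOccurrence\n"
    "#f int\tfloat\tint\tint\tint\tfloat\tfloat\tint\tint\n"
)

_XMAP_HEADER = (
    "# XMAP File Version:\t0.2\n"
    "#h XmapEntryID\tQryContigID\tRefContigID\tQryStartPos\tQryEndPos\tRefStartPos\tRefEndPos"
    "\tOrientation\tConfidence\tHitEnum\tQryLen\tRefLen\tLabelChannel\tAlignment\n"
    "#f int\tint\tint\tfloat\tfloat\tfloat\tfloat\tstring\tfloat\tstring\tfloat\tfloat\tint\tstring\n"
)

_DECOY_OFFSET_BP = 10000.0
_QRY_MARGIN_BP = 1000.0


def _cmap_rows(map_obj: LabelMap) -> str:
    rows = []
    n_sites = len(map_obj.positions)
    for site_id, pos in map_obj.positions:
        rows.append(
            f"{map_obj.map_id}\t{map_obj.length_bp:.3f}\t{n_sites}\t{site_id}\t1\t{pos:.3f}\t0.0\t1\t1\n"
        )
    # channel-end sentinel row
    rows.append(
        f"{map_obj.map_id}\t{map_obj.length_bp:.3f}\t{n_sites}\t{n_sites + 1}\t0\t{map_obj.length_bp:.3f}\t0.0\t1\t0\n"
    )
    return "".join(rows)


def build_fixture_maps(
    dset: DistanceSet, locus: LocusSpec
) -> tuple[LabelMap, list[LabelMap], list[MoleculeAlignment]]:
    """In-memory XMAP/CMAP trio from which extraction recovers ``dset``.

    Each molecule carries the two flanking labels plus two decoys; every
    other molecule is aligned in '-' orientation (label map mirrored) to
    exercise orientation independence.
    """
    left_id = locus.marker_left_id if locus.marker_left_id is not None else 2
    right_id = locus.marker_right_id if locus.marker_right_id is not None else 3
    ref_sites = sorted(
        [
            (min(left_id, right_id) - 1, locus.marker_left_pos - _DECOY_OFFSET_BP),
            (left_id, float(locus.marker_left_pos)),
            (right_id, float(locus.marker_right_pos)),
            (max(left_id, right_id) + 1, locus.marker_right_pos + _DECOY_OFFSET_BP),
        ]
    )
    ref_map = LabelMap(
        map_id=1,
        positions=ref_sites,
        length_bp=locus.marker_right_pos + 2 * _DECOY_OFFSET_BP,
    )
    qry_maps: list[LabelMap] = []
    alignments: list[MoleculeAlignment] = []
    for i, (mol_id, dist) in enumerate(zip(dset.molecule_ids, dset.distances_bp)):
        d = round(dist, 3)
        fwd = [
            _QRY_MARGIN_BP / 2,  # decoy
            _QRY_MARGIN_BP,  # left marker
            _QRY_MARGIN_BP + d,  # right marker
            _QRY_MARGIN_BP + d + _QRY_MARGIN_BP / 2,  # decoy
        ]
        length = fwd[-1] + _QRY_MARGIN_BP / 2
        reverse = i % 2 == 1
        if reverse:
            positions = sorted(length - p for p in fwd)
            # mirrored map: site k now sits where site (5-k) was
            pairs = [
                (ref_sites[0][0], 4),
                (left_id, 3),
                (right_id, 2),
                (ref_sites[-1][0], 1),
            ]
        else:
            positions = fwd
            pairs = [
                (ref_sites[0][0], 1),
                (left_id, 2),
                (right_id, 3),
                (ref_sites[-1][0], 4),
            ]
        qry_maps.append(
            LabelMap(
                map_id=mol_id,
                positions=[(j + 1, float(p)) for j, p in enumerate(positions)],
                length_bp=float(length),
            )
        )
        alignments.append(
            MoleculeAlignment(
                molecule_id=mol_id,
                ref_contig_id=1,
                orientation="-" if reverse else "+",
                pairs=pairs,
                confidence=20.0,
            )
        )
    return ref_map, qry_maps, alignments


def write_alignment_fixture(
    dset: DistanceSet, locus: LocusSpec, path_prefix: str
) -> tuple[str, str, str]:
    """Write a minimal XMAP + reference/query CMAP trio to disk.

    Returns (xmap_path, ref_cmap_path, qry_cmap_path).  Round trip through
    the extraction path reproduces the distances to 3 decimal places.
    """
    ref_map, qry_maps, alignments = build_fixture_maps(dset, locus)
    xmap_path = f"{path_prefix}.xmap"
    ref_path = f"{path_prefix}_r.cmap"
    qry_path = f"{path_prefix}_q.cmap"
    with open(ref_path, "w") as fh:
        fh.write(_CMAP_HEADER)
        fh.write(_cmap_rows(ref_map))
    with open(qry_path, "w") as fh:
        fh.write(_CMAP_HEADER)
        for qmap in qry_maps:
            fh.write(_cmap_rows(qmap))
    with open(xmap_path, "w") as fh:
        fh.write(_XMAP_HEADER)
        for entry_id, (aln, qmap) in enumerate(zip(alignments, qry_maps), start=1):
            alignment_str = "".join(f"({r},{q})" for r, q in aln.pairs)
            qry_positions = [qmap.position_of(q) for _, q in aln.pairs]
            ref_positions = [ref_map.position_of(r) for r, _ in aln.pairs]
            fh.write(
                f"{entry_id}\t{aln.molecule_id}\t1\t{min(qry_positions):.1f}\t{max(qry_positions):.1f}"
                f"\t{min(ref_positions):.1f}\t{max(ref_positions):.1f}\t{aln.orientation}"
                f"\t{aln.confidence:.2f}\t4M\t{qmap.length_bp:.1f}\t{ref_map.length_bp:.1f}\t1"
                f"\t{alignment_str}\n"
            )
    return xmap_path, ref_path, qry_path
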
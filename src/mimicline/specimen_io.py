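"""Specimen-table data model, TSV I/O, and 1D transect projection.

Specimens are individual bees with a collection location, caste (which
determines ploidy: drones are haploid males, queens and workers diploid
females), a color phenotype, an optional color-locus genotype, a
mitochondrial haplogroup, and a collection-period label.  Analyses run
along a one-dimensional north–south transect; each specimen's position
is its great-circle distance from the southernmost specimen measured
along a meridian (positive northward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

#: IUGG mean Earth radius in kilometres; fixed so distances are
#: bit-reproducible across machines.
EARTH_RADIUS_KM = 6371.0088

TSV_COLUMNS = [
    "id",
    "caste",
    "latitude",
    "longitude",
    "color_phenotype",
    "color_genotype",
    "mt_haplogroup",
    "period",
    "locality",
]


class ValidationError(ValueError):
    """A specimen record violates a biological or format invariant."""


class Caste(str, Enum):
    QUEEN = "queen"
    WORKER = "worker"
    DRONE = "drone"


class Ploidy(str, Enum):
    HAPLOID = "haploid"
    DIPLOID = "diploid"


class ColorPhenotype(str, Enum):
    FERRUGINOUS = "ferruginous"
    BLACK = "black"
    UNKNOWN = "unknown"


class ColorGenotype(str, Enum):
    FF = "ff"
    FB = "fb"
    BB = "bb"
    F = "f"
    B = "b"
    UNKNOWN = "unknown"


class MtHaplogroup(str, Enum):
    NORTHERN = "northern"
    SOUTHERN = "southern"
    UNKNOWN = "unknown"


_HAPLOID_GENOTYPES = {ColorGenotype.F, ColorGenotype.B, ColorGenotype.UNKNOWN}
_DIPLOID_GENOTYPES = {
    ColorGenotype.FF,
    ColorGenotype.FB,
    ColorGenotype.BB,
    ColorGenotype.UNKNOWN,
}


def project_to_transect(
    latitude: float,
    reference_latitude: float,
    *,
    longitude: float | None = None,
    reference_longitude: float | None = None,
    projection: str = "latitudinal",
) -> float:
    """Project a latitude onto the 1D transect, in kilometres.

    The default ``latitudinal`` projection measures the great-circle
    (haversine) distance between the two latitudes along a shared
    meridian, which reduces to an arc of a great circle:
    ``R * |Δlat| * π/180``.  The sign is positive north of the
    reference and negative south of it.

    The alternative ``great_circle`` projection uses the full 2D
    haversine distance between ``(latitude, longitude)`` and the
    reference point, signed by latitude; it requires both longitudes.

    Parameters
    ----------
    latitude, reference_latitude:
        Decimal degrees, each in [-90, 90].
    longitude, reference_longitude:
        Decimal degrees; required for ``projection="great_circle"``.
    projection:
        ``"latitudinal"`` (default) or ``"great_circle"``.
    """
    for name, lat in (("latitude", latitude), ("reference_latitude", reference_latitude)):
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"{name} {lat!r} outside [-90, 90]")
    if projection == "latitudinal":
        distance = EARTH_RADIUS_KM * math.radians(abs(latitude - reference_latitude))
    elif projection == "great_circle":
        if longitude is None or reference_longitude is None:
            raise ValidationError("great_circle projection requires both longitudes")
        distance = _haversine_km(reference_latitude, reference_longitude, latitude, longitude)
    else:
        raise ValidationError(f"unknown projection {projection!r}")
    return distance if latitude >= reference_latitude else -distance


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class SpecimenRecord:
    """One bee: location, ploidy, color, mtDNA haplogroup, period."""

    id: str
    caste: Caste
    latitude: float
    longitude: float
    color_phenotype: ColorPhenotype = ColorPhenotype.UNKNOWN
    color_genotype: ColorGenotype = ColorGenotype.UNKNOWN
    mt_haplogroup: MtHaplogroup = MtHaplogroup.UNKNOWN
    period: str = ""
    locality: str = ""
    transect_km: float = float("nan")

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.id}: latitude {self.latitude} outside [-90, 90]")
        if self.ploidy is Ploidy.HAPLOID:
            if self.color_genotype not in _HAPLOID_GENOTYPES:
                raise ValidationError(
                    f"{self.id}: haploid drone cannot carry diploid genotype "
                    f"{self.color_genotype.value!r}"
                )
        elif self.color_genotype not in _DIPLOID_GENOTYPES:
            raise ValidationError(
                f"{self.id}: diploid {self.caste.value} cannot carry haploid genotype "
                f"{self.color_genotype.value!r}"
            )
        self._check_dominance()

    @property
    def ploidy(self) -> Ploidy:
        return Ploidy.HAPLOID if self.caste is Caste.DRONE else Ploidy.DIPLOID

    def _check_dominance(self) -> None:
        # ferruginous f is dominant over black b: fb females are
        # ferruginous; black phenotype implies bb (females) or b (males)
        geno, pheno = self.color_genotype, self.color_phenotype
        if pheno is ColorPhenotype.UNKNOWN or geno is ColorGenotype.UNKNOWN:
            return
        expected = (
            ColorPhenotype.BLACK
            if geno in (ColorGenotype.BB, ColorGenotype.B)
            else ColorPhenotype.FERRUGINOUS
        )
        if pheno is not expected:
            raise ValidationError(
                f"{self.id}: genotype {geno.value!r} implies phenotype "
                f"{expected.value!r} under ferruginous dominance, got {pheno.value!r}"
            )


@dataclass
class SpecimenTable:
    """Ordered collection of specimens sharing one transect coordinate system.

    ``transect_reference_latitude`` is the latitude of the southernmost
    specimen, so published transect positions are >= 0.
    """

    records: list[SpecimenRecord] = field(default_factory=list)
    transect_reference_latitude: float = float("nan")
    projection: str = "latitudinal"

    @classmethod
    def from_records(
        cls, records: Iterable[SpecimenRecord], projection: str = "latitudinal"
    ) -> "SpecimenTable":
        records = list(records)
        if not records:
            raise ValidationError("specimen table is empty")
        southernmost = min(records, key=lambda r: r.latitude)
        projected = [
            replace(
                r,
                transect_km=project_to_transect(
                    r.latitude,
                    southernmost.latitude,
                    longitude=r.longitude,
                    reference_longitude=southernmost.longitude,
                    projection=projection,
                ),
            )
            for r in records
        ]
        return cls(projected, southernmost.latitude, projection)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def subset(self, predicate) -> "SpecimenTable":
        """Records satisfying ``predicate``, keeping the shared transect."""
        kept = [r for r in self.records if predicate(r)]
        return SpecimenTable(kept, self.transect_reference_latitude, self.projection)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "caste": r.caste.value,
                    "latitude": r.latitude,
                    "longitude": r.longitude,
                    "color_phenotype": r.color_phenotype.value,
                    "color_genotype": r.color_genotype.value,
                    "mt_haplogroup": r.mt_haplogroup.value,
                    "period": r.period,
                    "locality": r.locality,
                    "transect_km": r.transect_km,
                }
            )
        return pd.DataFrame(rows, columns=TSV_COLUMNS + ["transect_km"])

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        for col in ("color_phenotype", "color_genotype", "mt_haplogroup"):
            df[col] = df[col].replace("unknown", "NA")
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def _parse_enum(cls, value: str, record_id: str, column: str):
    if pd.isna(value) or value in ("NA", ""):
        return cls.UNKNOWN
    try:
        return cls(value)
    except ValueError as exc:
        raise ValidationError(f"{record_id}: bad {column} value {value!r}") from exc


def load_specimens(path: str | Path, projection: str = "latitudinal") -> SpecimenTable:
    """Load a specimen TSV, validate records, and project to the transect.

    Unknown phenotype/genotype/haplogroup are encoded as ``NA`` and kept;
    per-analysis exclusion happens downstream.  A dominance violation
    (e.g. genotype ``fb`` recorded with phenotype ``black``) raises a
    :class:`ValidationError` naming the offending specimens.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA"])
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    records: list[SpecimenRecord] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        try:
            records.append(
                SpecimenRecord(
                    id=rid,
                    caste=Caste(row["caste"]),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    color_phenotype=_parse_enum(
                        ColorPhenotype, row["color_phenotype"], rid, "color_phenotype"
                    ),
                    color_genotype=_parse_enum(
                        ColorGenotype, row["color_genotype"], rid, "color_genotype"
                    ),
                    mt_haplogroup=_parse_enum(
                        MtHaplogroup, row["mt_haplogroup"], rid, "mt_haplogroup"
                    ),
                    period="" if pd.isna(row["period"]) else str(row["period"]),
                    locality="" if pd.isna(row["locality"]) else str(row["locality"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError("invalid specimen rows: " + "; ".join(errors))
    return SpecimenTable.from_records(records, projection=projection)
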
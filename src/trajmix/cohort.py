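"""Longitudinal cohort data model, I/O and quality control.

The central container is :class:`LongitudinalCohort`: a set of subjects, each
with two or more imaging visits at irregular ages, carrying one median
fractional-anisotropy (FA) value per white-matter region per visit plus
subject-level covariates (sex, APOE4 carriership and optional biomarkers).
Time is parameterized as years since age 60, so a trajectory intercept is the
FA level at age 60 and the slope is the annual change thereafter.

Regions are described by a :class:`RegionManifest` naming each tract and its
fibre class (commissural / association / projection / brainstem / superficial)
and depth class (deep / superficial). The packaged default manifest contains
48 midline-merged tracts: 28 deep and 20 superficial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FIBRE_CLASSES = ("commissural", "association", "projection", "brainstem", "superficial")
DEPTH_CLASSES = ("deep", "superficial")

#: Long-format visit table columns that are not FA regions.
RESERVED_COLUMNS = ("subject_id", "age_at_scan", "sex", "apoe4")

#: Amyloid-PET positivity cutpoint on the SUVR scale (centiloid 19).
AMYLOID_SUVR_CUTPOINT = 1.48

#: Subject-level covariate columns recognized in visit tables. Any other
#: column name is assumed to be a region id and must appear in the manifest.
KNOWN_COVARIATES = (
    "apoe2",
    "education_years",
    "cmc_count",
    "amyloid_suvr",
    "wmh_fraction",
    "gait_speed",
    "cognitive_global",
    "cognitive_memory",
    "cognitive_executive",
    "cognitive_language",
    "cognitive_visuospatial",
    "true_label",
)


@dataclass(frozen=True)
class Region:
    region_id: str
    name: str
    fibre_class: str
    depth_class: str

    def __post_init__(self) -> None:
        if self.fibre_class not in FIBRE_CLASSES:
            raise ValueError(f"unknown fibre_class {self.fibre_class!r}")
        if self.depth_class not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth_class {self.depth_class!r}")
        # superficial WM is its own fibre class; the two labels must agree
        if (self.fibre_class == "superficial") != (self.depth_class == "superficial"):
            raise ValueError(
                f"region {self.region_id!r}: fibre_class 'superficial' must "
                "coincide with depth_class 'superficial'"
            )


class RegionManifest:
    """Ordered collection of :class:`Region` entries with unique ids."""

    def __init__(self, regions: Iterable[Region]):
        self.regions = list(regions)
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region_ids: {dupes}")
        self._index = {r.region_id: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._index

    def __getitem__(self, region_id: str) -> Region:
        return self._index[region_id]

    def __iter__(self):
        return iter(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def count(self, *, depth_class: str | None = None, fibre_class: str | None = None) -> int:
        n = 0
        for r in self.regions:
            if depth_class is not None and r.depth_class != depth_class:
                continue
            if fibre_class is not None and r.fibre_class != fibre_class:
                continue
            n += 1
        return n

    def subset(self, region_ids: Sequence[str]) -> "RegionManifest":
        missing = [r for r in region_ids if r not in self._index]
        if missing:
            raise KeyError(f"region_ids not in manifest: {missing}")
        return RegionManifest(self._index[r] for r in region_ids)

    @classmethod
    def from_json(cls, path) -> "RegionManifest":
        with open(path) as fh:
            entries = json.load(fh)
        return cls(Region(**e) for e in entries)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {
                        "region_id": r.region_id,
                        "name": r.name,
                        "fibre_class": r.fibre_class,
                        "depth_class": r.depth_class,
                    }
                    for r in self.regions
                ],
                fh,
                indent=1,
            )

    @classmethod
    def default(cls) -> "RegionManifest":
        """The packaged 48-tract manifest (28 deep, 20 superficial).

        Tract names follow the midline-merged JHU/Eve atlas conventions; the
        fibre-class assignment follows standard JHU groupings. The exact
        region list of any particular study may differ — the manifest is
        editable and validated only on label consistency.
        """
        ref = resources.files("trajmix.data") / "default_manifest.json"
        with resources.as_file(ref) as path:
            manifest = cls.from_json(path)
        assert len(manifest) == 48
        assert manifest.count(depth_class="superficial") == 20
        assert manifest.count(depth_class="deep") == 28
        return manifest


@dataclass
class VisitRecord:
    subject_id: str
    age_at_scan: float
    fa: dict[str, float]  # region_id -> FA; np.nan marks missing

    @property
    def time(self) -> float:
        """Years since age 60 (the model's time origin)."""
        return self.age_at_scan - 60.0


@dataclass
class SubjectRecord:
    subject_id: str
    sex: int  # 1 = female, 0 = male (reference)
    apoe4: int  # 1 = carrier, 0 = non-carrier (reference)
    covariates: dict[str, float] = field(default_factory=dict)
    visits: list[VisitRecord] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


class LongitudinalCohort:
    """Subjects with repeated regional-FA measurements.

    Parameters
    ----------
    subjects
        One :class:`SubjectRecord` per participant, visits sorted by age.
    manifest
        Region manifest; every FA key must appear in it.
    zscored
        Whether the FA columns have been standardized to pooled mean 0 / SD 1.
    zscore_constants
        ``{region_id: (mean, sd)}`` recorded by :func:`zscore_regions` so the
        raw scale can be recovered.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        manifest: RegionManifest,
        zscored: bool = False,
        zscore_constants: Mapping[str, tuple[float, float]] | None = None,
    ):
        self.subjects = list(subjects)
        self.manifest = manifest
        self.zscored = zscored
        self.zscore_constants = dict(zscore_constants or {})
        self._validate()

    def _validate(self) -> None:
        known = set(self.manifest.region_ids)
        for s in self.subjects:
            ages = [v.age_at_scan for v in s.visits]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError(f"subject {s.subject_id}: visit ages not strictly increasing")
            for v in s.visits:
                unknown = set(v.fa) - known
                if unknown:
                    raise ValueError(
                        f"subject {s.subject_id}: FA regions not in manifest: {sorted(unknown)}"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.manifest)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per subject x visit."""
        rows = []
        for s in self.subjects:
            for v in s.visits:
                row: dict = {
                    "subject_id": s.subject_id,
                    "age_at_scan": v.age_at_scan,
                    "sex": s.sex,
                    "apoe4": s.apoe4,
                }
                row.update(s.covariates)
                for rid in self.manifest.region_ids:
                    row[rid] = v.fa.get(rid, np.nan)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_arrays(self) -> dict:
        """Pack the cohort into padded numpy arrays for the samplers.

        Returns a dict with keys ``t`` (N, J) times, ``y`` (N, J, R) FA,
        ``obs`` (N, J, R) bool observation mask, ``visit_mask`` (N, J),
        ``sex`` (N,), ``apoe4`` (N,), ``subject_ids``, ``region_ids``.
        Padded cells hold zeros and are masked out.
        """
        N = self.n_subjects
        rids = self.manifest.region_ids
        R = len(rids)
        J = max((s.n_visits for s in self.subjects), default=0)
        t = np.zeros((N, J))
        y = np.zeros((N, J, R))
        obs = np.zeros((N, J, R), dtype=bool)
        visit_mask = np.zeros((N, J), dtype=bool)
        sex = np.zeros(N)
        apoe4 = np.zeros(N)
        for i, s in enumerate(self.subjects):
            sex[i] = s.sex
            apoe4[i] = s.apoe4
            for j, v in enumerate(s.visits):
                visit_mask[i, j] = True
                t[i, j] = v.time
                for r, rid in enumerate(rids):
                    val = v.fa.get(rid, np.nan)
                    if np.isfinite(val):
                        y[i, j, r] = val
                        obs[i, j, r] = True
        return {
            "t": t,
            "y": y,
            "obs": obs,
            "visit_mask": visit_mask,
            "sex": sex,
            "apoe4": apoe4,
            "subject_ids": [s.subject_id for s in self.subjects],
            "region_ids": rids,
        }

    def baseline_matrix(self) -> np.ndarray:
        """First-visit FA, shape (n_subjects, n_regions); NaN where missing."""
        rids = self.manifest.region_ids
        out = np.full((self.n_subjects, len(rids)), np.nan)
        for i, s in enumerate(self.subjects):
            if s.visits:
                for r, rid in enumerate(rids):
                    out[i, r] = s.visits[0].fa.get(rid, np.nan)
        return out


# ---------------------------------------------------------------------------
# I/O


def read_cohort(visits_path, manifest_path) -> LongitudinalCohort:
    """Read a long-format visit CSV plus a JSON region manifest.

    The CSV must carry ``subject_id, age_at_scan, sex, apoe4`` and one column
    per manifest region; any other column is preserved as a subject-level
    covariate (taken from the first visit). Empty cells are missing FA, never
    zero. Rows are grouped per subject and sorted by age.
    """
    manifest = RegionManifest.from_json(manifest_path)
    # round_trip parsing: the default C float parser can drop the last ulp
    df = pd.read_csv(visits_path, float_precision="round_trip")
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"visits table missing required column {col!r}")
    covar_cols = [
        c
        for c in df.columns
        if c not in RESERVED_COLUMNS
        and c not in manifest
        and (c in KNOWN_COVARIATES or c.startswith("cov_"))
    ]
    region_cols = [c for c in df.columns if c in manifest]
    unknown = [
        c
        for c in df.columns
        if c not in RESERVED_COLUMNS and c not in region_cols and c not in covar_cols
    ]
    if unknown:
        raise ValueError(f"FA columns not present in manifest: {unknown}")
    dup = df.duplicated(subset=["subject_id", "age_at_scan"])
    if dup.any():
        bad = df.loc[dup, ["subject_id", "age_at_scan"]].values.tolist()
        raise ValueError(f"duplicate (subject, age) rows: {bad[:5]}")
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("age_at_scan")
        first = grp.iloc[0]
        covariates = {}
        for c in covar_cols:
            val = first[c]
            covariates[c] = float(val) if np.isfinite(pd.to_numeric(val, errors="coerce")) else np.nan
        visits = []
        for _, row in grp.iterrows():
            fa = {}
            for rid in region_cols:
                val = row[rid]
                fa[rid] = float(val) if pd.notna(val) else np.nan
            visits.append(VisitRecord(str(sid), float(row["age_at_scan"]), fa))
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                sex=int(first["sex"]),
                apoe4=int(first["apoe4"]),
                covariates=covariates,
                visits=visits,
            )
        )
    return LongitudinalCohort(subjects, manifest)


def write_cohort(cohort: LongitudinalCohort, visits_path, manifest_path) -> None:
    """Write the cohort as visit CSV + manifest JSON (inverse of read_cohort)."""
    df = cohort.to_frame()
    # pandas' default shortest-repr float formatting round-trips doubles
    df.to_csv(visits_path, index=False)
    cohort.manifest.to_json(manifest_path)


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcReport:
    dropped_regions: dict[str, str] = field(default_factory=dict)
    dropped_subjects: dict[str, str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.dropped_regions and not self.dropped_subjects

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dropped_regions": self.dropped_regions,
                    "dropped_subjects": self.dropped_subjects,
                },
                fh,
                indent=1,
            )


def apply_qc(
    cohort: LongitudinalCohort,
    min_visits: int = 2,
    fa_floor: float = 0.25,
    max_missing_frac: float = 0.2,
) -> tuple[LongitudinalCohort, QcReport]:
    """Inclusion filtering applied before standardization and clustering.

    Drops regions whose cohort-wide median first-visit FA falls below
    ``fa_floor`` (such regions are mostly grey matter or boundary voxels),
    then subjects with fewer than ``min_visits`` visits or with more than
    ``max_missing_frac`` of their region x visit FA cells missing
    (suggestive of registration failure). Requires raw (unstandardized) FA
    so the floor is meaningful.
    """
    if cohort.zscored:
        raise ValueError("apply_qc expects raw FA; cohort is already z-scored")
    report = QcReport()
    base = cohort.baseline_matrix()
    rids = cohort.manifest.region_ids
    keep_regions = []
    for r, rid in enumerate(rids):
        col = base[:, r]
        med = np.nanmedian(col) if np.isfinite(col).any() else np.nan
        if np.isfinite(med) and med < fa_floor:
            report.dropped_regions[rid] = f"median baseline FA {med:.3f} < {fa_floor}"
        else:
            keep_regions.append(rid)
    if not keep_regions:
        raise ValueError("QC dropped all regions")
    sub_manifest = cohort.manifest.subset(keep_regions)
    kept_subjects = []
    for s in cohort.subjects:
        if s.n_visits < min_visits:
            report.dropped_subjects[s.subject_id] = (
                f"{s.n_visits} visit(s) < required {min_visits}"
            )
            continue
        n_cells = s.n_visits * len(keep_regions)
        n_missing = sum(
            0 if np.isfinite(v.fa.get(rid, np.nan)) else 1
            for v in s.visits
            for rid in keep_regions
        )
        frac = n_missing / n_cells if n_cells else 1.0
        if frac > max_missing_frac:
            report.dropped_subjects[s.subject_id] = (
                f"missing fraction {frac:.2f} > {max_missing_frac}"
            )
            continue
        visits = [
            VisitRecord(
                v.subject_id,
                v.age_at_scan,
                {rid: v.fa.get(rid, np.nan) for rid in keep_regions},
            )
            for v in s.visits
        ]
        kept_subjects.append(
            SubjectRecord(s.subject_id, s.sex, s.apoe4, dict(s.covariates), visits)
        )
    if not kept_subjects:
        raise ValueError("QC dropped all subjects")
    return LongitudinalCohort(kept_subjects, sub_manifest), report


# ---------------------------------------------------------------------------
# Standardization


def zscore_regions(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Standardize each region to pooled mean 0 / SD 1 over all observations.

    Constants are stored on the returned cohort so :func:`inverse_zscore`
    can recover the raw scale exactly.
    """
    if cohort.zscored:
        raise ValueError("cohort is already z-scored")
    rids = cohort.manifest.region_ids
    pooled: dict[str, list[float]] = {rid: [] for rid in rids}
    for s in cohort.subjects:
        for v in s.visits:
            for rid in rids:
                val = v.fa.get(rid, np.nan)
                if np.isfinite(val):
                    pooled[rid].append(val)
    constants = {}
    for rid in rids:
        vals = np.asarray(pooled[rid])
        if vals.size == 0:
            raise ValueError(f"region {rid!r} has no observations")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"region {rid!r} has zero variance")
        constants[rid] = (mean, sd)
    subjects = [
        SubjectRecord(
            s.subject_id,
            s.sex,
            s.apoe4,
            dict(s.covariates),
            [
                VisitRecord(
                    v.subject_id,
                    v.age_at_scan,
                    {
                        rid: (v.fa[rid] - constants[rid][0]) / constants[rid][1]
                        if np.isfinite(v.fa.get(rid, np.nan))
                        else np.nan
                        for rid in rids
                    },
                )
                for v in s.visits
            ],
        )
        for s in cohort.subjects
    ]
    return LongitudinalCohort(subjects, cohort.manifest, zscored=True, zscore_constants=constants)


def inverse_zscore(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Map a z-scored cohort back to the raw FA scale."""
    if not cohort.zscored:
        raise ValueError("cohort is not z-scored")
    if not cohort.zscore_constants:
        raise ValueError("cohort lacks stored standardization constants")
    c = cohort.zscore_constants
    subjects = [
        SubjectRecord(
            s.subject_id,
            s.sex,
            s.apoe4,
            dict(s.covariates),
            [
                VisitRecord(
                    v.subject_id,
                    v.age_at_scan,
                    {
                        rid: v.fa[rid] * c[rid][1] + c[rid][0]
                        if np.isfinite(v.fa.get(rid, np.nan))
                        else np.nan
                        for rid in cohort.manifest.region_ids
                    },
                )
                for v in s.visits
            ],
        )
        for s in cohort.subjects
    ]
    return LongitudinalCohort(subjects, cohort.manifest, zscored=False)


def classify_amyloid(suvr: float, cutpoint: float = AMYLOID_SUVR_CUTPOINT) -> str:
    """Dichotomize an amyloid-PET SUVR: 'abnormal' iff strictly above cutpoint."""
    if not np.isfinite(suvr) or suvr <= 0:
        raise ValueError(f"SUVR must be positive, got {suvr}")
    return "abnormal" if suvr > cutpoint else "normal"
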
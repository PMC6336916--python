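"""End-to-end orchestration: simulate -> features -> normalize -> detect.

The stages mirror the detection procedure: multimodal per-vertex features
are extracted for both hemispheres of every subject, smoothed (10 mm FWHM),
z-scored within subject and then against the control cohort per vertex,
and finally fed to the subject-level cross-validated PCA + neural-network
classifier.  The report aggregates patient-level detection into confusion
metrics, Cohen's kappa against the resection-defined ground truth, and the
cluster tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from . import io as fio
from .classify import (ANNConfig, CrossValidationResult, SubjectFeatures,
                       cross_validate)
from .evaluate import ConfusionCounts, cohens_kappa, confusion_metrics
from .features import (FeatureBundle, cortical_thickness, doughnut_map,
                       flair_profile, gwc, interhemispheric_asymmetry,
                       local_cortical_deformation, pet_hypointensity,
                       sulcal_depth)
from .normalize import (ControlCohortStats, fit_control_stats, smooth_fwhm,
                        smoothing_operator, zscore_between_subjects,
                        zscore_within_subject)
from .surface import (HomotopicCorrespondence, geodesic_distances,
                      mean_curvature)
from .synthetic import CohortSpec, SyntheticSubject, generate_cohort


@dataclass
class PipelineConfig:
    """Every tunable stage parameter, with the pipeline defaults."""

    fwhm: float = 10.0                 # smoothing kernel, mm
    gm_fraction: float = 0.30          # GWC gray sample depth
    wm_depth_mm: float = 1.0           # GWC white sample depth
    pet_depth_fraction: float = 0.5    # PET sampling depth
    doughnut_radius: float = 6.0       # mm, on the inflated surface
    lcd_radius: float = 25.0           # mm geodesic disc
    retained_variance: float = 0.95    # PCA target
    hidden_sizes: tuple[int, ...] = (10,)
    learning_rate: float = 1e-3
    max_epochs: int = 400
    k_folds: int = 5
    cv_iterations: int = 100
    min_area_mm2: float = 25.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hidden_sizes" in d:
            d = {**d, "hidden_sizes": tuple(d["hidden_sizes"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    def ann_config(self, seed: int | None = None) -> ANNConfig:
        return ANNConfig(hidden_sizes=self.hidden_sizes,
                         learning_rate=self.learning_rate,
                         max_epochs=self.max_epochs,
                         seed=self.seed if seed is None else seed)


# ----------------------------------------------------------------------
# feature extraction
# ----------------------------------------------------------------------

def extract_features(pairs, inflated, volumes, corr: HomotopicCorrespondence,
                     config: PipelineConfig | None = None
                     ) -> dict[str, FeatureBundle]:
    """Raw (unsmoothed, unnormalized) feature bundles for both hemispheres.

    ``pairs``/``inflated`` map 'lh'/'rh' to surfaces, ``volumes`` holds the
    co-registered 't1', 'flair' and 'pet' scalar volumes.
    """
    config = config or PipelineConfig()
    bundles: dict[str, FeatureBundle] = {}
    pet_maps = pet_hypointensity(volumes["pet"], pairs["lh"], pairs["rh"],
                                 depth_fraction=config.pet_depth_fraction)
    # inflated hemispheres are exact mirrors: one distance matrix serves both
    doughnut_dist = geodesic_distances(inflated["lh"],
                                       limit=2 * config.doughnut_radius)
    for hemi, pet_map in zip(("lh", "rh"), pet_maps):
        pair = pairs[hemi]
        b = FeatureBundle(n_vertices=pair.n_vertices)
        b.add(cortical_thickness(pair))
        b.add(gwc(volumes["t1"], pair, config.gm_fraction,
                  config.wm_depth_mm))
        b.add(mean_curvature(pair.white))
        b.add(sulcal_depth(pair.pial))
        b.add(local_cortical_deformation(pair.pial, config.lcd_radius))
        for smap in flair_profile(volumes["flair"], pair).values():
            b.add(smap)
        b.add(pet_map)
        for name in ("gwc", "thickness", "flair_50"):
            b.add(doughnut_map(b[name], inflated[hemi],
                               config.doughnut_radius,
                               distances=doughnut_dist))
        bundles[hemi] = b
    # interhemispheric asymmetry of every base feature
    base_names = list(bundles["lh"].names)
    for name in base_names:
        asym_l, asym_r = interhemispheric_asymmetry(
            bundles["lh"][name], bundles["rh"][name], corr)
        bundles["lh"].add(asym_l)
        bundles["rh"].add(asym_r)
    return bundles


def extract_subject(subject: SyntheticSubject,
                    config: PipelineConfig | None = None) -> SubjectFeatures:
    """Extract raw features for one synthetic subject."""
    geom = subject.geometry()
    bundles = extract_features(geom["pairs"], geom["inflated"],
                               subject.volumes(), geom["corr"], config)
    return SubjectFeatures(
        subject_id=subject.subject_id,
        bundles=bundles,
        corr=geom["corr"],
        meshes={h: geom["pairs"][h].pial for h in ("lh", "rh")},
        group=subject.group,
        lesion_hemi=subject.lesion_hemi,
        lesion=subject.lesion_label(),
        resection=subject.resection_label())


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def smooth_subject(sf: SubjectFeatures, fwhm: float) -> SubjectFeatures:
    """Smooth every feature map on the subject's white-matter surface."""
    out_bundles = {}
    for hemi, bundle in sf.bundles.items():
        mesh = sf.meshes[hemi]
        op = smoothing_operator(mesh, fwhm)
        nb = FeatureBundle(n_vertices=bundle.n_vertices)
        for name in bundle.names:
            nb.add(smooth_fwhm(bundle[name], mesh, fwhm, operator=op))
        out_bundles[hemi] = nb
    return dataclasses.replace(sf, bundles=out_bundles)


def zscore_subject(sf: SubjectFeatures) -> SubjectFeatures:
    out_bundles = {}
    for hemi, bundle in sf.bundles.items():
        nb = FeatureBundle(n_vertices=bundle.n_vertices)
        for name in bundle.names:
            nb.add(zscore_within_subject(bundle[name]))
        out_bundles[hemi] = nb
    return dataclasses.replace(sf, bundles=out_bundles)


def normalize_cohort(subjects: list[SubjectFeatures],
                     config: PipelineConfig | None = None
                     ) -> tuple[list[SubjectFeatures],
                                dict[str, ControlCohortStats]]:
    """Smooth, z-score within subject, then z-score against controls.

    Control statistics are fitted per hemisphere on the smoothed,
    within-subject-normalized maps of the control subjects only.
    Returns the fully normalized subjects and the per-hemisphere stats.
    """
    config = config or PipelineConfig()
    staged = [zscore_subject(smooth_subject(sf, config.fwhm))
              for sf in subjects]
    controls = [sf for sf in staged if not sf.is_patient]
    if len(controls) < 2:
        raise ValueError("need at least 2 control subjects for "
                         "between-subject normalization")
    stats: dict[str, ControlCohortStats] = {}
    for hemi in ("lh", "rh"):
        per_feature = {name: [sf.bundles[hemi][name] for sf in controls]
                       for name in controls[0].bundles[hemi].names}
        stats[hemi] = fit_control_stats(per_feature)
    normalized = []
    for sf in staged:
        out_bundles = {}
        for hemi, bundle in sf.bundles.items():
            nb = FeatureBundle(n_vertices=bundle.n_vertices)
            for name in bundle.names:
                nb.add(zscore_between_subjects(bundle[name], stats[hemi]))
            out_bundles[hemi] = nb
        normalized.append(dataclasses.replace(sf, bundles=out_bundles))
    return normalized, stats


# ----------------------------------------------------------------------
# end to end
# ----------------------------------------------------------------------

def prepare_cohort(spec: CohortSpec,
                   config: PipelineConfig | None = None
                   ) -> list[SubjectFeatures]:
    """Generate a cohort and run it through extraction and normalization."""
    subjects, _ = generate_cohort(spec)
    raw = [extract_subject(s, config) for s in subjects]
    normalized, _ = normalize_cohort(raw, config)
    return normalized


def run_all(spec: CohortSpec, config: PipelineConfig | None = None,
            k: int | None = None, iterations: int | None = None,
            seed: int | None = None) -> dict:
    """Full pipeline on a synthetic cohort; returns the evaluation report.

    The report carries the config echo and seeds, the cross-validation
    aggregate (mean +/- sd of sensitivity/specificity/accuracy over folds x
    iterations), majority-vote per-subject calls with the derived confusion
    metrics and Cohen's kappa, and the per-subject concordance table.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    normalized = prepare_cohort(spec, config)
    cv = cross_validate(normalized,
                        k=k or config.k_folds,
                        iterations=iterations or config.cv_iterations,
                        seed=seed,
                        retained_variance=config.retained_variance,
                        ann_config=config.ann_config(),
                        min_area_mm2=config.min_area_mm2)
    return build_report(cv, spec, config, seed)


def build_report(cv: CrossValidationResult, spec: CohortSpec,
                 config: PipelineConfig, seed: int) -> dict:
    per = cv.per_subject
    pat = per[per.group == "patient"]
    con = per[per.group == "control"]
    tp = int((pat.times_detected > 0.5 * pat.times_held_out).sum())
    fn = len(pat) - tp
    fp = int((con.times_flagged > 0.5 * con.times_held_out).sum())
    tn = len(con) - fp
    counts = ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
    metrics = confusion_metrics(counts)
    kappa = cohens_kappa(counts.as_table())
    return {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "cohort_spec": dataclasses.asdict(spec),
        "cv_aggregate": cv.aggregate,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "metrics": metrics,
        "kappa": kappa,
        "detection_rate": cv.detection_rate,
        "control_fp_rate": cv.control_fp_rate,
        "per_subject": per.to_dict(orient="records"),
    }


# ----------------------------------------------------------------------
# on-disk cohort loading (CLI staged pipeline)
# ----------------------------------------------------------------------

def manifest_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class LoadedSubject:
    """A subject read back from a materialized cohort directory."""

    subject_id: str
    group: str
    pairs: dict
    inflated: dict
    corr: HomotopicCorrespondence
    volumes: dict
    lesion_hemi: str | None = None
    lesion: object = None
    resection: object = None

    def geometry(self) -> dict:
        return {"pairs": self.pairs, "inflated": self.inflated,
                "corr": self.corr}


def load_cohort(cohort_dir) -> list:
    """Read a cohort written by :func:`fcdsurf.synthetic.write_cohort`."""
    cohort_dir = Path(cohort_dir)
    mpath = cohort_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(
            f"{mpath} not found: run the 'simulate' stage first")
    manifest = json.loads(mpath.read_text())
    subjects = []
    for entry in manifest["subjects"]:
        paths = entry["paths"]
        pairs, inflated = {}, {}
        from .surface import CorticalSurfacePair
        for hemi in ("lh", "rh"):
            white = fio.read_surface(cohort_dir / paths[f"{hemi}_white"])
            pial = fio.read_surface(cohort_dir / paths[f"{hemi}_pial"])
            pairs[hemi] = CorticalSurfacePair(white=white, pial=pial)
            inflated[hemi] = fio.read_surface(
                cohort_dir / paths[f"{hemi}_inflated"])
        volumes = {name: fio.read_volume(cohort_dir / paths[name])
                   for name in ("t1", "flair", "pet")}
        subj = LoadedSubject(
            subject_id=entry["subject_id"], group=entry["group"],
            pairs=pairs, inflated=inflated,
            corr=HomotopicCorrespondence.identity(
                pairs["lh"].n_vertices),
            volumes=volumes, lesion_hemi=entry.get("lesion_hemi"))
        if "lesion" in paths:
            subj.lesion = fio.read_label(cohort_dir / paths["lesion"])
            subj.lesion.name = "lesion"
        if "resection" in paths:
            subj.resection = fio.read_label(cohort_dir / paths["resection"])
            subj.resection.name = "resection"
        subjects.append(subj)
    return subjects


def extract_loaded_subject(subject: LoadedSubject,
                           config: PipelineConfig | None = None
                           ) -> SubjectFeatures:
    bundles = extract_features(subject.pairs, subject.inflated,
                               subject.volumes, subject.corr, config)
    return SubjectFeatures(
        subject_id=subject.subject_id,
        bundles=bundles,
        corr=subject.corr,
        meshes={h: subject.pairs[h].pial for h in ("lh", "rh")},
        group=subject.group,
        lesion_hemi=subject.lesion_hemi,
        lesion=subject.lesion,
        resection=subject.resection)
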
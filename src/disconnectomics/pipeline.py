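"""End-to-end driver: simulation → pairing → disconnectomes → components →
associations → voxel maps → atlas → embedding QC.

Each stage writes its artefacts under ``out_dir/<stage>/`` together with a
completion marker listing output checksums; a re-run loads completed stages
from disk and recomputes only from the first missing stage onwards. The run
manifest contains the configuration echo, per-stage parameters and output
checksums — and deliberately no wall-clock data, so that two runs with the
same seed produce byte-identical manifests (timing goes to ``run.log``).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas_summary import build_atlas
from .components import fit_component_model, variance_curve
from .config import PipelineConfig
from .datatypes import LesionMask, DisconnectomeMap
from .disconnectome import disconnectome_cohort
from .embedding_qc import embed_2d, flatten_maps, separation_statistic
from .io import read_table, read_tractogram, read_volume, write_table, write_tractogram, write_volume
from .lesion_synthesis import SynthPoolConfig, build_synthetic_pool, match_lesions
from .parcel_features import build_feature_matrix
from .synthetic_data import (
    PlantedStructure,
    default_connection_pairs,
    make_toy_brain,
    make_toy_term_maps,
    make_toy_tractograms,
    plant_lesion_cohort,
    planted_bundle_structure,
)
from .term_association import TermMatrix, bootstrap_ttest, component_term_correlations, condition_summary
from .voxel_statistics import component_voxel_maps, split_half_replicate, term_voxel_maps

__all__ = ["RunManifest", "run_pipeline"]

STAGES = [
    "simulate",
    "synth_lesions",
    "disconnectomes",
    "features",
    "components",
    "associations",
    "component_maps",
    "term_maps",
    "atlas",
    "embedding",
]


@dataclass
class ExternalSpace:
    """Minimal common-space container for user-supplied (non-simulated) data."""

    brain_mask: np.ndarray
    hemisphere_labels: np.ndarray
    parcellation: np.ndarray
    affine: np.ndarray
    voxel_size: tuple


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_outputs(stage_dir: Path) -> dict:
    return {
        str(p.relative_to(stage_dir.parent)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file() and p.name != ".done.json"
    }


class _Runner:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.manifest = RunManifest(config=config.to_dict())
        self.log_path = self.out / "run.log"
        self._dirty = False  # becomes True once any stage recomputes

    def log(self, msg: str) -> None:
        with open(self.log_path, "a") as fh:
            fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}\n")

    def run_stage(self, name: str, compute, load, params: dict):
        stage_dir = self.out / name
        marker = stage_dir / ".done.json"
        if marker.exists() and not self._dirty:
            recorded = json.loads(marker.read_text())
            outputs_ok = all((self.out / rel).exists() for rel in recorded["outputs"])
            if outputs_ok and recorded.get("params") == _jsonable(params):
                load(stage_dir)
                self.manifest.stages[name] = recorded
                self.log(f"stage {name}: cached")
                return
        self._dirty = True
        if stage_dir.exists():
            for p in sorted(stage_dir.rglob("*"), reverse=True):
                p.unlink() if p.is_file() else p.rmdir()
        stage_dir.mkdir(parents=True, exist_ok=True)
        self.log(f"stage {name}: computing")
        compute(stage_dir)
        record = {"params": _jsonable(params), "outputs": _checksum_outputs(stage_dir)}
        marker.write_text(json.dumps(record, indent=2, sort_keys=True))
        self.manifest.stages[name] = record

    # ------------------------------------------------------------------ stages

    def simulate(self, d: Path):
        cfg = self.cfg
        spec = make_toy_brain(cfg.grid_shape, cfg.regions_per_hemisphere, seed=cfg.seed)
        pairs = default_connection_pairs(spec)
        planted_pairs = pairs[: cfg.n_patterns]
        structure = planted_bundle_structure(
            spec, planted_pairs, cfg.n_terms, noise_sd=cfg.term_noise_sd, seed=cfg.seed
        )
        tractograms = make_toy_tractograms(
            spec, pairs, cfg.n_subjects, cfg.streamlines_per_pair, cfg.jitter_sd, seed=cfg.seed + 1
        )
        cohort = plant_lesion_cohort(
            spec,
            structure,
            cfg.n_lesions,
            "clustered",
            cfg.lesion_size_range,
            seed=cfg.seed + 2,
            dispersion_mm=cfg.cluster_dispersion_mm,
            id_prefix="stroke",
        )
        terms = make_toy_term_maps(structure, spec.n_regions, seed=cfg.seed + 3)

        write_volume(spec.brain_mask, spec.affine, d / "brain_mask.nii")
        write_volume(spec.hemisphere_labels, spec.affine, d / "hemispheres.nii")
        write_volume(spec.parcellation, spec.affine, d / "parcellation.nii")
        write_volume(spec.wm_mask, spec.affine, d / "wm_mask.nii")
        write_table(spec.region_table, d / "regions.tsv", index=False)
        for tg in tractograms:
            write_tractogram(tg, d / f"{tg.subject_id}.trk")
        meta = []
        for les in cohort:
            write_volume(les.volume, spec.affine, d / "lesions" / f"{les.id}.nii")
            meta.append({"id": les.id, "hemisphere": les.hemisphere, "size_vox": les.size_vox})
        write_table(pd.DataFrame(meta), d / "lesions.tsv", index=False)
        write_table(terms.to_dataframe(), d / "term_matrix.tsv")
        write_table(
            pd.DataFrame(structure.pattern_region_profiles, columns=spec.region_ids),
            d / "planted_profiles.tsv",
        )
        self.state.update(
            spec=spec, structure=structure, tractograms=tractograms, cohort=cohort, terms=terms
        )

    def load_simulate(self, d: Path):
        # geometry is regenerated (deterministic) and cross-checked against disk
        self.simulate_in_memory()
        parc, _ = read_volume(d / "parcellation.nii")
        if not np.array_equal(parc, self.state["spec"].parcellation):
            raise ValueError("cached simulation does not match this configuration")

    def simulate_in_memory(self):
        cfg = self.cfg
        spec = make_toy_brain(cfg.grid_shape, cfg.regions_per_hemisphere, seed=cfg.seed)
        pairs = default_connection_pairs(spec)
        structure = planted_bundle_structure(
            spec, pairs[: cfg.n_patterns], cfg.n_terms, noise_sd=cfg.term_noise_sd, seed=cfg.seed
        )
        tractograms = make_toy_tractograms(
            spec, pairs, cfg.n_subjects, cfg.streamlines_per_pair, cfg.jitter_sd, seed=cfg.seed + 1
        )
        cohort = plant_lesion_cohort(
            spec,
            structure,
            cfg.n_lesions,
            "clustered",
            cfg.lesion_size_range,
            seed=cfg.seed + 2,
            dispersion_mm=cfg.cluster_dispersion_mm,
            id_prefix="stroke",
        )
        terms = make_toy_term_maps(structure, spec.n_regions, seed=cfg.seed + 3)
        self.state.update(
            spec=spec, structure=structure, tractograms=tractograms, cohort=cohort, terms=terms
        )

    def load_external(self, _d: Path | None = None):
        """Assemble the common-space container from user-supplied files."""
        cfg = self.cfg
        parc, affine = read_volume(cfg.parcellation_path)
        parc = parc.astype(np.int32)
        if cfg.brain_mask_path is not None:
            brain, _ = read_volume(cfg.brain_mask_path)
            brain = brain > 0
        else:
            brain = parc > 0
        if cfg.hemisphere_labels_path is not None:
            hemi, _ = read_volume(cfg.hemisphere_labels_path)
            hemi = hemi.astype(np.int8)
        else:
            # split at the mid-sagittal world plane; on-plane voxels go left
            idx = np.indices(parc.shape).reshape(3, -1).T
            world_x = (idx @ affine[:3, :3].T + affine[:3, 3])[:, 0].reshape(parc.shape)
            hemi = np.where(world_x <= 0, 1, 2).astype(np.int8)
            hemi[~brain] = 0
        lesions = []
        for p in sorted(Path(cfg.lesions_dir).glob("*.nii*")):
            vol, _ = read_volume(p)
            mask = vol > 0
            codes, counts = np.unique(hemi[mask], return_counts=True)
            hemisphere = "left" if codes[np.argmax(counts)] != 2 else "right"
            lesions.append(
                LesionMask(
                    volume=mask,
                    hemisphere=hemisphere,
                    size_vox=int(mask.sum()),
                    source="observed",
                    id=p.stem.replace(".nii", ""),
                )
            )
        if not lesions:
            raise ValueError(f"no lesion volumes found under {cfg.lesions_dir}")
        tractograms = [
            read_tractogram(p) for p in sorted(Path(cfg.tractograms_dir).glob("*.t[rc]k"))
        ]
        if not tractograms:
            raise ValueError(f"no tractograms found under {cfg.tractograms_dir}")
        df = read_table(cfg.term_matrix_path)
        terms = TermMatrix(
            values=df.to_numpy(), term_names=list(df.index), region_ids=[int(c) for c in df.columns]
        )
        self.state.update(
            spec=ExternalSpace(
                brain_mask=brain,
                hemisphere_labels=hemi,
                parcellation=parc,
                affine=affine,
                voxel_size=tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0))),
            ),
            structure=None,
            tractograms=tractograms,
            cohort=lesions,
            terms=terms,
        )

    def synth_lesions(self, d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        pool = build_synthetic_pool(
            spec.brain_mask,
            spec.hemisphere_labels,
            SynthPoolConfig(
                k_values=list(cfg.k_values),
                fwhm_mm=cfg.fwhm_mm,
                threshold=cfg.polish_threshold,
                seed=cfg.seed,
            ),
            voxel_size=spec.voxel_size,
            affine=spec.affine,
        )
        matched = match_lesions(
            self.state["cohort"], pool, size_tolerance=cfg.size_tolerance, seed=cfg.seed
        )
        rows = []
        for i, (obs, syn) in enumerate(zip(self.state["cohort"], matched)):
            syn_id = f"synth-{i:04d}"
            write_volume(syn.volume, spec.affine, d / "lesions" / f"{syn_id}.nii")
            rows.append(
                {
                    "observed_id": obs.id,
                    "synthetic_id": syn_id,
                    "pool_id": syn.id,
                    "observed_size": obs.size_vox,
                    "synthetic_size": syn.size_vox,
                    "hemisphere": obs.hemisphere,
                }
            )
        write_table(pd.DataFrame(rows), d / "pairing.tsv", index=False)
        self.state["synthetic"] = matched

    def load_synth_lesions(self, d: Path):
        spec = self.state["spec"]
        pairing = read_table(d / "pairing.tsv", index_col=None)
        matched = []
        for _, row in pairing.iterrows():
            vol, _ = read_volume(d / "lesions" / f"{row.synthetic_id}.nii")
            matched.append(
                LesionMask(
                    volume=vol > 0,
                    hemisphere=row.hemisphere,
                    size_vox=int((vol > 0).sum()),
                    source="synthetic",
                    id=str(row.pool_id),
                )
            )
        self.state["synthetic"] = matched
        del spec

    def disconnectomes(self, d: Path):
        spec = self.state["spec"]
        for key, cohort in (("cohort", "stroke"), ("synthetic", "synthetic")):
            maps = disconnectome_cohort(self.state[key], self.state["tractograms"])
            self.state[f"dmaps_{cohort}"] = maps
            for m in maps:
                write_volume(m.volume, spec.affine, d / cohort / f"{m.lesion_id}.nii", dtype=np.float32)

    def load_disconnectomes(self, d: Path):
        n_sub = len(self.state["tractograms"])
        for key, cohort in (("cohort", "stroke"), ("synthetic", "synthetic")):
            maps = []
            for les in self.state[key]:
                vol, _ = read_volume(d / cohort / f"{les.id}.nii")
                maps.append(DisconnectomeMap(volume=vol, lesion_id=les.id, n_subjects=n_sub))
            self.state[f"dmaps_{cohort}"] = maps

    CONDITION_SOURCES = {
        "stroke_lesion": ("cohort", "lesion"),
        "stroke_disconnectome": ("dmaps_stroke", "map"),
        "synthetic_lesion": ("synthetic", "lesion"),
        "synthetic_disconnectome": ("dmaps_synthetic", "map"),
    }

    def features(self, d: Path):
        parc = self.state["spec"].parcellation
        for condition, (key, _) in self.CONDITION_SOURCES.items():
            fm = build_feature_matrix(self.state[key], parc, condition)
            self.state[f"features_{condition}"] = fm
            write_table(fm.to_dataframe(), d / f"{condition}.tsv")

    def load_features(self, d: Path):
        from .parcel_features import FeatureMatrix

        for condition in self.CONDITION_SOURCES:
            df = read_table(d / f"{condition}.tsv")
            self.state[f"features_{condition}"] = FeatureMatrix(
                values=df.to_numpy(),
                observation_ids=list(df.index),
                region_ids=[int(c) for c in df.columns],
                condition=condition,
            )

    def components(self, d: Path):
        cfg = self.cfg
        for condition in self.CONDITION_SOURCES:
            fm = self.state[f"features_{condition}"]
            model = fit_component_model(
                fm,
                retention=cfg.retention,
                m=cfg.retention_m,
                max_iter=cfg.varimax_max_iter,
                tol=cfg.varimax_tol,
                kaiser_normalize=cfg.kaiser_normalize,
            )
            curve = variance_curve(fm)
            self.state[f"model_{condition}"] = model
            self.state[f"curve_{condition}"] = curve
            sub = d / condition
            ids = fm.region_ids
            names = [f"component_{i + 1:02d}" for i in range(model.m)]
            write_table(pd.DataFrame(model.loadings, index=ids, columns=names), sub / "loadings.tsv")
            write_table(
                pd.DataFrame(model.score_coefficients, index=ids, columns=names),
                sub / "score_coefficients.tsv",
            )
            write_table(
                pd.DataFrame(model.scores, index=fm.observation_ids, columns=names), sub / "scores.tsv"
            )
            write_table(
                pd.DataFrame({"eigenvalue": model.eigenvalues}), sub / "eigenvalues.tsv"
            )
            write_table(pd.DataFrame({"r2": curve.r2_by_m}), sub / "variance_curve.tsv")
            (sub / "model.json").write_text(
                json.dumps(
                    {
                        "m": model.m,
                        "retention": cfg.retention,
                        "kaiser_normalize": cfg.kaiser_normalize,
                        "varimax_max_iter": cfg.varimax_max_iter,
                        "seed": cfg.seed,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )

    def load_components(self, _d: Path):
        # deterministic refit from the cached feature matrices
        self.components_in_memory()

    def components_in_memory(self):
        cfg = self.cfg
        for condition in self.CONDITION_SOURCES:
            fm = self.state[f"features_{condition}"]
            self.state[f"model_{condition}"] = fit_component_model(
                fm,
                retention=cfg.retention,
                m=cfg.retention_m,
                max_iter=cfg.varimax_max_iter,
                tol=cfg.varimax_tol,
                kaiser_normalize=cfg.kaiser_normalize,
            )
            self.state[f"curve_{condition}"] = variance_curve(fm)

    def associations(self, d: Path):
        cfg = self.cfg
        terms = self.state["terms"]
        summaries = {}
        for condition in self.CONDITION_SOURCES:
            model = self.state[f"model_{condition}"]
            assoc = component_term_correlations(model.score_coefficients, terms)
            self.state[f"assoc_{condition}"] = assoc
            frames = assoc.to_dataframe()
            for name, df in frames.items():
                write_table(df, d / condition / f"{name}.tsv")
            per_comp, mean = condition_summary(assoc, mode=cfg.summary_mode)
            summaries[condition] = {"per_component": per_comp.tolist(), "mean": mean}
        comparisons = {}
        for a, b in (
            ("stroke_disconnectome", "stroke_lesion"),
            ("stroke_disconnectome", "synthetic_disconnectome"),
        ):
            t, p = bootstrap_ttest(
                summaries[a]["per_component"],
                summaries[b]["per_component"],
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
            comparisons[f"{a}_vs_{b}"] = {"t": t, "p_boot": p}
        payload = {"summaries": summaries, "comparisons": comparisons, "mode": cfg.summary_mode}
        (d / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        self.state["association_summary"] = payload

    def load_associations(self, d: Path):
        terms = self.state["terms"]
        for condition in self.CONDITION_SOURCES:
            model = self.state[f"model_{condition}"]
            self.state[f"assoc_{condition}"] = component_term_correlations(
                model.score_coefficients, terms
            )
        self.state["association_summary"] = json.loads((d / "summary.json").read_text())

    def component_maps(self, d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        model = self.state["model_stroke_disconnectome"]
        dmaps = self.state["dmaps_stroke"]
        mask = spec.brain_mask
        maps = component_voxel_maps(dmaps, model.scores, mask, n_perm=cfg.n_perm, seed=cfg.seed)
        self.state["component_maps"] = maps
        sidecar = {"n_perm": cfg.n_perm, "seed": cfg.seed}
        for i, name in enumerate(maps.unit_names):
            write_volume(np.nan_to_num(maps.stat[i]), spec.affine, d / f"{name}_tstat.nii", sidecar=sidecar)
            write_volume(np.nan_to_num(maps.p[i], nan=1.0), spec.affine, d / f"{name}_pperm.nii")
            write_volume(np.nan_to_num(maps.r[i]), spec.affine, d / f"{name}_r.nii")
        if cfg.split_half and len(dmaps) >= 6:
            rep = split_half_replicate(
                dmaps, spec.parcellation, mask, n_perm=min(cfg.n_perm, 100), seed=cfg.seed
            )
            (d / "split_half.json").write_text(
                json.dumps(
                    {"r_values": rep.r_values.tolist(), "mean": rep.mean, "sd": rep.sd},
                    indent=2,
                    sort_keys=True,
                )
            )
            self.state["split_half"] = rep

    def load_component_maps(self, _d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        model = self.state["model_stroke_disconnectome"]
        self.state["component_maps"] = component_voxel_maps(
            self.state["dmaps_stroke"], model.scores, spec.brain_mask, n_perm=cfg.n_perm, seed=cfg.seed
        )

    def term_maps(self, d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        maps = term_voxel_maps(
            self.state["component_maps"],
            self.state["assoc_stroke_disconnectome"],
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        self.state["term_maps"] = maps
        for i, name in enumerate(maps.unit_names):
            write_volume(np.nan_to_num(maps.stat[i]), spec.affine, d / f"{name}_tstat.nii")
            write_volume(np.nan_to_num(maps.p[i], nan=1.0), spec.affine, d / f"{name}_pperm.nii")
            write_volume(np.nan_to_num(maps.r[i]), spec.affine, d / f"{name}_r.nii")

    def load_term_maps(self, _d: Path):
        cfg = self.cfg
        self.state["term_maps"] = term_voxel_maps(
            self.state["component_maps"],
            self.state["assoc_stroke_disconnectome"],
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )

    def atlas(self, d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        summary = build_atlas(
            self.state["term_maps"],
            display_p=cfg.display_p,
            versatility_threshold=cfg.versatility_threshold,
        )
        self.state["atlas"] = summary
        write_volume(summary.label_volume, spec.affine, d / "atlas_labels.nii")
        write_volume(summary.r_volume, spec.affine, d / "atlas_effect_size.nii")
        write_volume(summary.versatility_volume, spec.affine, d / "atlas_versatility.nii")
        legend = pd.DataFrame(
            [{"index": k, "term": v} for k, v in summary.label_legend.items()]
        )
        write_table(legend, d / "atlas_legend.tsv", index=False)

    def load_atlas(self, d: Path):
        pass  # terminal artefacts; nothing downstream consumes them

    def embedding(self, d: Path):
        cfg = self.cfg
        spec = self.state["spec"]
        results = {}
        for kind, obs_key, syn_key in (
            ("lesion", "cohort", "synthetic"),
            ("disconnectome", "dmaps_stroke", "dmaps_synthetic"),
        ):
            obs = self.state[obs_key]
            syn = self.state[syn_key]
            vols = [getattr(o, "volume") for o in obs] + [getattr(s, "volume") for s in syn]
            labels = ["stroke"] * len(obs) + ["synthetic"] * len(syn)
            X = flatten_maps(vols, spec.brain_mask)
            emb = embed_2d(
                X,
                perplexity=cfg.perplexity,
                exaggeration=cfg.exaggeration,
                learning_rate=cfg.learning_rate,
                iterations=cfg.tsne_iterations,
                seed=cfg.seed,
                labels=labels,
            )
            sep = separation_statistic(X, labels)
            results[kind] = {"separation": sep, "settings": emb.settings}
            df = pd.DataFrame(emb.coordinates, columns=["tsne_1", "tsne_2"])
            df["label"] = labels
            write_table(df, d / f"{kind}_embedding.tsv", index=False)
        (d / "separation.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        self.state["embedding_summary"] = results

    def load_embedding(self, d: Path):
        self.state["embedding_summary"] = json.loads((d / "separation.json").read_text())


def _jsonable(obj):
    return json.loads(json.dumps(obj, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order; returns the manifest (also written to disk)."""
    r = _Runner(config)
    cfg = config
    common = {"seed": cfg.seed}
    if cfg.simulate:
        r.run_stage(
            "simulate",
            r.simulate,
            r.load_simulate,
            {**common, "grid_shape": list(cfg.grid_shape), "n_lesions": cfg.n_lesions},
        )
    else:
        r.load_external()
        r._dirty = True  # external inputs are not checksum-tracked; always recompute
    r.run_stage(
        "synth_lesions",
        r.synth_lesions,
        r.load_synth_lesions,
        {**common, "fwhm_mm": cfg.fwhm_mm, "threshold": cfg.polish_threshold, "k_values": list(cfg.k_values)},
    )
    r.run_stage("disconnectomes", r.disconnectomes, r.load_disconnectomes, common)
    r.run_stage("features", r.features, r.load_features, common)
    r.run_stage(
        "components",
        r.components,
        r.load_components,
        {**common, "retention": cfg.retention, "varimax_max_iter": cfg.varimax_max_iter},
    )
    r.run_stage(
        "associations",
        r.associations,
        r.load_associations,
        {**common, "n_boot": cfg.n_boot, "mode": cfg.summary_mode},
    )
    r.run_stage(
        "component_maps", r.component_maps, r.load_component_maps, {**common, "n_perm": cfg.n_perm}
    )
    r.run_stage("term_maps", r.term_maps, r.load_term_maps, {**common, "n_perm": cfg.n_perm})
    r.run_stage(
        "atlas",
        r.atlas,
        r.load_atlas,
        {**common, "display_p": cfg.display_p, "versatility_threshold": cfg.versatility_threshold},
    )
    r.run_stage(
        "embedding",
        r.embedding,
        r.load_embedding,
        {**common, "perplexity": cfg.perplexity, "iterations": cfg.tsne_iterations},
    )
    manifest_path = r.out / "manifest.json"
    manifest_path.write_text(r.manifest.to_json() + "\n")
    r.log("pipeline complete")
    return r.manifest
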
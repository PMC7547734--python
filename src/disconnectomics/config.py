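"""Pipeline configuration: one validated object, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage parameters, with the study defaults, plus the global seed.

    In ``simulate`` mode the toy-brain generator provides every input; with
    ``simulate=False`` the four path fields must point at existing data.
    """

    out_dir: str = "disconnectomics_out"
    simulate: bool = True
    seed: int = 0

    # external inputs (ignored when simulate=True)
    lesions_dir: str | None = None
    tractograms_dir: str | None = None
    parcellation_path: str | None = None
    term_matrix_path: str | None = None
    brain_mask_path: str | None = None
    hemisphere_labels_path: str | None = None

    # simulation scale
    grid_shape: tuple = (16, 16, 16)
    regions_per_hemisphere: int = 4
    n_lesions: int = 60
    n_subjects: int = 4
    streamlines_per_pair: int = 40
    jitter_sd: float = 1.5
    n_patterns: int = 4
    n_terms: int = 12
    term_noise_sd: float = 0.05
    lesion_size_range: tuple = (8, 40)
    cluster_dispersion_mm: float = 2.0

    # synthetic-lesion pool + pairing
    fwhm_mm: float = 10.0
    polish_threshold: float = 0.3
    k_values: list = field(default_factory=lambda: list(range(2, 65)))
    size_tolerance: float = 0.1

    # components
    retention: str = "kaiser_mean"
    retention_m: int | None = None
    varimax_max_iter: int = 500
    varimax_tol: float = 1e-6
    kaiser_normalize: bool = True

    # association
    summary_mode: str = "max_per_component"
    n_boot: int = 1000

    # voxel statistics
    n_perm: int = 1000
    split_half: bool = True

    # atlas
    display_p: float = 0.05
    versatility_threshold: float = 0.3
    large_effect_threshold: float = 0.5

    # embedding QC
    perplexity: float = 30.0
    exaggeration: float = 12.0
    learning_rate: float = 200.0
    tsne_iterations: int = 1000

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.lesion_size_range = tuple(int(s) for s in self.lesion_size_range)
        checks = [
            (self.fwhm_mm >= 0, "fwhm_mm must be >= 0"),
            (0 < self.polish_threshold < 1, "polish_threshold must be in (0, 1)"),
            (all(k >= 1 for k in self.k_values), "k_values must be >= 1"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.n_boot >= 1, "n_boot must be >= 1"),
            (self.varimax_max_iter >= 1, "varimax_max_iter must be >= 1"),
            (self.perplexity > 0, "perplexity must be > 0"),
            (0 < self.display_p <= 1, "display_p must be in (0, 1]"),
            (self.versatility_threshold >= 0, "versatility_threshold must be >= 0"),
            (self.size_tolerance >= 0, "size_tolerance must be >= 0"),
            (self.retention in ("kaiser_mean", "fixed", "target_r2"), "unknown retention rule"),
            (self.summary_mode in ("max_per_component", "mean_all_pairs"), "unknown summary mode"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        if not self.simulate:
            missing = [
                name
                for name in ("lesions_dir", "tractograms_dir", "parcellation_path", "term_matrix_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"simulate=False requires paths: {missing}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["lesion_size_range"] = list(self.lesion_size_range)
        return d
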
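"""Configuration, file formats and end-to-end orchestration.

One :class:`RunConfig` (YAML-serializable) fully determines a run:
recordings are band-pass filtered and epoched, projected to source space
with the LCMV beamformer, parcellated, turned into per-subject PLV
matrices, tested with NBS, and every surviving subnetwork is summarized
(strength ANCOVA, Spearman correlations with the cognitive scores, LOO
logistic classification).  A manifest with the config, package versions
and per-file SHA-256 checksums makes re-runs verifiable: the pipeline
output is a pure function of the input files and the config.

File formats: recordings and leadfields are HDF5 (written without
timestamps so equal runs are byte-identical), metadata is comma-separated
UTF-8 CSV with a header row, FC matrices are HDF5 plus a long-format TSV,
results are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import DEFAULT_EDGE_FRACTION, fc_matrix
from .downstream import (
    loo_logistic_classify,
    spearman_correlations,
    strength_ancova,
    subnetwork_strength,
)
from .nbs import NBSError, SubjectTable, nbs_permutation
from .preprocess import (
    BANDS,
    BandSpec,
    SensorRecording,
    TrialRejectionError,
    epoch_and_equalize,
    filter_twopass,
)
from .sourcerecon import (
    LeadField,
    apply_sensor_scaling,
    average_trial_covariance,
    lcmv_weights,
    normalize_leadfield_by_type,
    parcellate_pca,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    recordings: str
    leadfield: str
    metadata: str
    output_dir: str
    bands: list[str] = field(default_factory=lambda: ["gamma"])
    trial_length: float = 4.0
    n_keep: int = 20
    z_threshold: float = 5.0
    regularization: float = 0.15
    edge_fraction: float = DEFAULT_EDGE_FRACTION
    p_threshold: float = 0.005
    min_fraction: float = 0.10
    n_perm: int = 5000
    alpha: float = 0.05
    ci_method: str = "clopper-pearson"
    seed: int = 0

    def validate(self) -> None:
        for path_field in ("recordings", "leadfield", "metadata"):
            if not Path(getattr(self, path_field)).exists():
                raise PipelineError(f"{path_field} path does not exist: "
                                    f"{getattr(self, path_field)}")
        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise PipelineError(f"unknown band names {unknown}; known: {list(BANDS)}")
        if not (0 < self.p_threshold < 1 and 0 < self.min_fraction < 1):
            raise PipelineError("p_threshold and min_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError(f"config file {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_recordings(recordings: list[SensorRecording], path: str | Path) -> None:
    """HDF5 store: one group per subject with a channels x samples dataset."""
    with h5py.File(path, "w") as fh:
        for rec in recordings:
            grp = fh.create_group(rec.subject_id)
            dset = grp.create_dataset("data", data=rec.data, track_times=False)
            dset.attrs["sampling_rate"] = rec.sampling_rate
            grp.create_dataset(
                "channel_types",
                data=np.array(rec.channel_types, dtype="S"),
                track_times=False,
            )


def read_recordings(path: str | Path) -> list[SensorRecording]:
    recordings = []
    with h5py.File(path, "r") as fh:
        for subject_id in sorted(fh.keys()):
            grp = fh[subject_id]
            recordings.append(
                SensorRecording(
                    data=grp["data"][()],
                    sampling_rate=float(grp["data"].attrs["sampling_rate"]),
                    channel_types=[
                        t.decode() for t in grp["channel_types"][()]
                    ],
                    subject_id=subject_id,
                )
            )
    return recordings


def write_leadfield(leadfield: LeadField, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=leadfield.matrix, track_times=False)
        fh.create_dataset(
            "sensor_types",
            data=np.array(leadfield.sensor_types, dtype="S"),
            track_times=False,
        )
        fh.create_dataset(
            "source_labels",
            data=np.array(leadfield.source_labels, dtype="S"),
            track_times=False,
        )


def read_leadfield(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as fh:
        return LeadField(
            matrix=fh["matrix"][()],
            sensor_types=[t.decode() for t in fh["sensor_types"][()]],
            source_labels=[t.decode() for t in fh["source_labels"][()]],
        )


def write_metadata(table: SubjectTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def read_metadata(path: str | Path) -> SubjectTable:
    """Read and validate a subject-metadata CSV.

    Schema problems (missing columns, duplicate ids, NaN in required
    fields) are reported with row numbers; ragged rows surface the parser's
    line number.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise NBSError(f"malformed metadata CSV {path}: {exc}") from exc
    return SubjectTable(frame=frame)


def write_fc_stack(
    stack: np.ndarray,
    subject_ids: list[str],
    band: str,
    h5_path: str | Path,
    tsv_path: str | Path | None = None,
    roi_names: list[str] | None = None,
) -> None:
    """Per-subject FC matrices as HDF5, optionally plus a long-format TSV."""
    with h5py.File(h5_path, "w") as fh:
        dset = fh.create_dataset("plv", data=stack, track_times=False)
        dset.attrs["band"] = band
        fh.create_dataset(
            "subject_ids", data=np.array(subject_ids, dtype="S"), track_times=False
        )
        if roi_names is not None:
            fh.create_dataset(
                "roi_names", data=np.array(roi_names, dtype="S"), track_times=False
            )
    if tsv_path is not None:
        n_rois = stack.shape[1]
        iu = np.triu_indices(n_rois, k=1)
        names = roi_names if roi_names else [str(k) for k in range(n_rois)]
        rows = []
        for sid, matrix in zip(subject_ids, stack):
            for i, j in zip(*iu):
                rows.append((sid, band, names[i], names[j], matrix[i, j]))
        pd.DataFrame(
            rows, columns=["subject", "band", "roi_i", "roi_j", "plv"]
        ).to_csv(tsv_path, sep="\t", index=False)


def read_fc_stack(h5_path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    with h5py.File(h5_path, "r") as fh:
        stack = fh["plv"][()]
        subject_ids = [s.decode() for s in fh["subject_ids"][()]]
        roi_names = (
            [s.decode() for s in fh["roi_names"][()]] if "roi_names" in fh else []
        )
    return stack, subject_ids, roi_names


def save_cohort(cohort, directory: str | Path) -> Path:
    """Write a synthetic cohort to disk in the pipeline's input formats.

    Emits ``recordings.h5``, ``leadfield.h5``, ``metadata.csv`` and
    ``ground_truth.json`` (planted links, couplings, per-subject true
    strength) under ``directory``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_recordings(cohort.recordings, directory / "recordings.h5")
    write_leadfield(cohort.leadfield, directory / "leadfield.h5")
    write_metadata(cohort.metadata, directory / "metadata.csv")
    with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)
    return directory


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _subject_fc(
    recording: SensorRecording,
    band: BandSpec,
    leadfield: LeadField,
    config: RunConfig,
    epoch_seed: np.random.SeedSequence,
) -> np.ndarray:
    """Preprocess -> beamform -> parcellate -> PLV for one subject/band."""
    filtered = filter_twopass(recording, band)
    normalized_lf, factors = normalize_leadfield_by_type(leadfield)
    filtered.data = apply_sensor_scaling(
        filtered.data, recording.channel_types, factors
    )
    trials = epoch_and_equalize(
        filtered,
        trial_length=config.trial_length,
        n_keep=config.n_keep,
        seed=np.random.default_rng(epoch_seed),
        z_threshold=config.z_threshold,
        band=band,
    )
    cov = average_trial_covariance(trials)
    model = lcmv_weights(cov, normalized_lf, regularization=config.regularization)
    source_data = model.apply(trials)
    roi_series = parcellate_pca(
        source_data,
        [[k] for k in range(normalized_lf.n_sources)],
        roi_names=list(normalized_lf.source_labels),
        band=band,
        sampling_rate=recording.sampling_rate,
        subject_id=recording.subject_id,
    )
    return fc_matrix(roi_series, edge_fraction=config.edge_fraction).values


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage for every band; returns the run directory.

    Subjects that fail trial equalization are excluded and logged; any
    other stage failure aborts with the stage name and subject id, keeping
    partial outputs in place for debugging.  Re-running with the same
    config and inputs reproduces identical manifest checksums.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = read_recordings(config.recordings)
    leadfield = read_leadfield(config.leadfield)
    table = read_metadata(config.metadata)

    ids_meta = list(table.frame["subject_id"])
    ids_rec = [r.subject_id for r in recordings]
    if ids_meta != ids_rec:
        missing = sorted(set(ids_meta) ^ set(ids_rec))
        raise PipelineError(
            f"metadata rows do not match recordings; mismatched subjects: {missing}"
        )

    root_ss = np.random.SeedSequence(config.seed)
    band_seeds = root_ss.spawn(len(config.bands))
    outputs: list[Path] = []
    results_summary: dict[str, dict] = {}

    for band_name, band_ss in zip(config.bands, band_seeds):
        band = BANDS[band_name]
        epoch_ss, nbs_ss = band_ss.spawn(2)
        subject_seeds = epoch_ss.spawn(len(recordings))
        fc_list, kept_ids = [], []
        for rec, subj_ss in zip(recordings, subject_seeds):
            try:
                fc_list.append(
                    _subject_fc(rec, band, leadfield, config, subj_ss)
                )
                kept_ids.append(rec.subject_id)
            except TrialRejectionError as exc:
                logger.warning("band %s: %s", band_name, exc)
            except Exception as exc:
                raise PipelineError(
                    f"stage subject_fc failed for band {band_name}, "
                    f"subject {rec.subject_id}: {exc}"
                ) from exc
        if len(fc_list) < 4:
            raise PipelineError(
                f"band {band_name}: fewer than 4 subjects survived preprocessing"
            )
        stack = np.stack(fc_list)
        kept_table = SubjectTable(
            frame=table.frame[table.frame["subject_id"].isin(kept_ids)]
            .reset_index(drop=True)
        )
        fc_path = out_dir / f"fc_{band_name}.h5"
        tsv_path = out_dir / f"fc_{band_name}.tsv"
        write_fc_stack(
            stack, kept_ids, band_name, fc_path, tsv_path, leadfield.source_labels
        )
        outputs += [fc_path, tsv_path]

        logger.info(
            "band %s: running NBS with %d permutations", band_name, config.n_perm
        )
        nbs_seed = int(np.random.default_rng(nbs_ss).integers(2**31 - 1))
        result = nbs_permutation(
            stack,
            kept_table,
            p_threshold=config.p_threshold,
            min_fraction=config.min_fraction,
            n_perm=config.n_perm,
            seed=nbs_seed,
        )

        band_results = {
            "band": band_name,
            "n_subjects": len(kept_ids),
            "n_permutations": config.n_perm,
            "nbs_seed": nbs_seed,
            "subnetworks": [
                s.to_dict(list(leadfield.source_labels)) for s in result.subnetworks
            ],
        }
        significant = [
            s for s in result.subnetworks
            if s.p_fwer is not None and s.p_fwer < config.alpha
        ]
        markers = {}
        for idx, sub in enumerate(significant):
            strength = subnetwork_strength(
                stack, sub, subnetwork_id=f"{band_name}_subnet{idx}", band=band_name
            )
            f_val, p_val = strength_ancova(strength, kept_table)
            correlations = spearman_correlations(
                {"strength": strength.values}, kept_table
            )
            report = loo_logistic_classify(
                strength.values,
                kept_table.group_indicator.astype(int),
                feature_name=f"{band_name}_subnet{idx}_strength",
                ci_method=config.ci_method,
            )
            markers[f"subnet{idx}"] = {
                "strength_mean_by_group": {
                    label: float(
                        strength.values[
                            (kept_table.frame["group"] == label).to_numpy()
                        ].mean()
                    )
                    for label in kept_table.group_labels
                },
                "strength_ancova": {"F": f_val, "p": p_val},
                "correlations": correlations.to_dict(orient="records"),
                "classification": report.as_dict(),
            }
        band_results["markers"] = markers
        results_summary[band_name] = band_results
        result_path = out_dir / f"nbs_{band_name}.json"
        with open(result_path, "w", encoding="utf-8") as fh:
            json.dump(band_results, fh, indent=2)
        outputs.append(result_path)

    config_blob = json.dumps(asdict(config), sort_keys=True)
    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "versions": {
            "megconn": __version__,
            "numpy": np.__version__,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
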
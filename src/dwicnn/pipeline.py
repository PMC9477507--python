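"""End-to-end simulation experiment: the seven-dataset comparison.

One run produces (1) a noise-free ground truth, (2) a low-noise and (3) a
high-noise corrupted dataset, and the four denoised datasets — each noise
level denoised by the 1D-CNN and by MP-PCA — then fits the tensor model to
all seven and writes an evaluation report (RMSE per shell, tissue-wise
correlations, FA/MD bias, high-b noise-floor index).

Training follows the train/test dataset split of the simulation design: the
model is fitted on one corrupted realization and applied to an
independently corrupted realization of the same phantom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cnn, dti, evaluation, mppca, noise, phantom
from .io import VoxelMatrix, to_voxel_matrix, write_dwi

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "run_experiment",
           "desk_profile"]

log = logging.getLogger("dwicnn")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Parameters of the full simulation experiment.

    Defaults are the full-scale reference settings (20000 epochs, learning
    rate 0.001, batch size 6000, MP-PCA extent 9x9x3, SNR 10 and 30); a
    desk-scale profile overrides the phantom size, epoch count, and
    training-voxel subsample.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 4)
    n_b0: int = 4
    dirs_per_shell: tuple[int, ...] = (90, 90)
    shell_bvals: tuple[float, ...] = (1000.0, 2000.0)
    combine: str = "sos"
    snr_low_noise: float = 30.0
    snr_high_noise: float = 10.0
    n_coils: int = 8
    epochs: int = 20000
    learning_rate: float = 0.001
    batch_size: int = 6000
    optimizer: str = "sgd"
    momentum: float = 0.0
    train_voxels: int | None = None
    mppca_extent: tuple[int, int, int] = (9, 9, 3)
    write_nifti: bool = False
    out_dir: str = "run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "dirs_per_shell", "shell_bvals", "mppca_extent"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.combine not in noise.COMBINES:
            raise ConfigError(f"unknown combine {self.combine!r}")
        if self.snr_low_noise <= 0 or self.snr_high_noise <= 0:
            raise ConfigError("SNR targets must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("invalid training parameters")


def desk_profile(seed: int = 0) -> RunConfig:
    """Desk-scale profile of the simulation experiment.

    Keeps the full phantom (64x64x4, T=184) and the SNR 10/30 noise levels
    but trains on a 1000-voxel subsample for 2000 epochs with the Adam
    optimizer (available behind ``DenoiserConfig``; the full-scale default
    remains plain SGD).  The optimizer choice follows the package's own
    hyper-parameter search on the simulated SNR-10 pair: at this sample
    size plain SGD needs either a very large step (whose gradient noise
    leaves the small CSF diffusion-weighted targets unresolved) or far
    more epochs, while Adam at the reference learning rate 0.001 reaches a
    training loss two orders of magnitude lower in the same epoch budget
    and resolves the CSF decay that the log-domain tensor fit is most
    sensitive to.
    """
    return RunConfig(
        seed=seed,
        epochs=2000,
        learning_rate=0.001,
        batch_size=250,
        optimizer="adam",
        train_voxels=1000,
    )


def run_experiment(cfg: RunConfig) -> evaluation.EvalReport:
    """Run the seven-dataset experiment in memory and return the report."""
    cfg.validate()
    log.info("simulating phantom %s seed=%d", cfg.shape, cfg.seed)
    proto = phantom.make_protocol(
        n_b0=cfg.n_b0,
        dirs_per_shell=cfg.dirs_per_shell,
        shell_bvals=cfg.shell_bvals,
        seed=cfg.seed,
    )
    ph = phantom.make_phantom(shape=cfg.shape, seed=cfg.seed)
    gt = phantom.simulate_noise_free(ph, proto)
    coil = noise.make_coil_model(
        cfg.shape, n_coils=cfg.n_coils, sigma=1.0, seed=cfg.seed + 1000
    )
    ref = noise.combine_noise_free(gt, coil, cfg.combine)

    datasets = {"ground_truth": ref}
    sigma_maps = {}
    models = {}
    rng = np.random.default_rng(cfg.seed)
    train_cfg = cnn.DenoiserConfig(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        optimizer=cfg.optimizer,
        momentum=cfg.momentum,
        seed=cfg.seed,
    )
    for tag, snr in (("snr%g" % cfg.snr_low_noise, cfg.snr_low_noise),
                     ("snr%g" % cfg.snr_high_noise, cfg.snr_high_noise)):
        sigma = noise.sigma_for_snr(gt, ph.labels, snr, cfg.combine, coil)
        c = coil.with_sigma(sigma)
        log.info("%s: sigma=%.4g", tag, sigma)
        noisy_train = noise.corrupt(gt, c, cfg.combine,
                                    seed=int(rng.integers(2**31)))
        noisy_test = noise.corrupt(gt, c, cfg.combine,
                                   seed=int(rng.integers(2**31)))
        datasets[f"noisy_{tag}"] = noisy_test
        vm_noisy = to_voxel_matrix(noisy_train)
        vm_ref = to_voxel_matrix(ref)
        if cfg.train_voxels is not None and cfg.train_voxels < vm_noisy.V:
            pick = rng.choice(vm_noisy.V, size=cfg.train_voxels, replace=False)
            vm_noisy = VoxelMatrix(vm_noisy.values[pick], vm_noisy.index[pick])
            vm_ref = VoxelMatrix(vm_ref.values[pick], vm_ref.index[pick])
        log.info("%s: training 1D-CNN on %d voxels, %d epochs",
                 tag, vm_noisy.V, cfg.epochs)
        model = cnn.train(vm_noisy, vm_ref, train_cfg, protocol=proto)
        models[tag] = model
        datasets[f"cnn_{tag}"] = cnn.denoise(model, noisy_test)
        log.info("%s: MP-PCA extent %s", tag, cfg.mppca_extent)
        dn, smap = mppca.mppca_denoise(
            noisy_test, mppca.PatchSpec(extent=cfg.mppca_extent)
        )
        datasets[f"mppca_{tag}"] = dn
        sigma_maps[tag] = smap

    log.info("fitting tensors on %d datasets", len(datasets))
    fits = {name: dti.fit_dti_wls(d) for name, d in datasets.items()}
    labels = ph.labels
    mask = gt.mask

    shells = [None] + [float(b) for b in proto.shells()]
    rmse_sec: dict = {}
    corr_sec: dict = {}
    floor_sec: dict = {}
    for name, d in datasets.items():
        if name == "ground_truth":
            continue
        rmse_sec[name] = {
            ("all" if s is None else "b%g" % s): evaluation.rmse(d, ref, shell=s)
            for s in shells
        }
        corr_sec[name] = {
            ("all" if s is None else "b%g" % s): {
                str(lab): r
                for lab, r in evaluation.shell_tissue_correlation(
                    d, ref, mask, labels, shell=s
                ).items()
            }
            for s in shells
        }
        floor_sec[name] = dti.high_b_floor_index(d, ref, labels, tissue=1)
    bias_sec = evaluation.metric_bias_report(
        {n: f for n, f in fits.items() if n != "ground_truth"},
        fits["ground_truth"],
        labels,
    )

    report = evaluation.EvalReport(
        sections={
            "rmse": rmse_sec,
            "correlations": corr_sec,
            "csf_high_b_floor_index": floor_sec,
            "metric_bias": bias_sec,
            "datasets": sorted(datasets),
            "final_training_loss": {
                tag: float(m.loss_history[-1]) for tag, m in models.items()
            },
        },
        provenance={
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "T": proto.T,
            "masked_voxels": int(mask.sum()),
        },
    )
    report._datasets = datasets  # runtime handle for callers; not serialized
    report._models = models
    report._phantom = ph
    return report


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full experiment from a YAML config; write the run directory.

    The run directory receives ``report.json``/``report.csv`` and, when
    ``write_nifti`` is set, every dataset as NIfTI + bval/bvec.  Idempotent
    for fixed seeds.
    """
    cfg = RunConfig.from_yaml(config_path)
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    try:
        report = run_experiment(cfg)
        report.to_json(out / "report.json")
        report.to_csv(out / "report.csv")
        if cfg.write_nifti:
            for name, d in report._datasets.items():
                write_dwi(
                    d,
                    out / f"{name}.nii.gz",
                    out / f"{name}.bval",
                    out / f"{name}.bvec",
                )
        for tag, model in report._models.items():
            cnn.save_model(model, out / f"model_{tag}.dwicnn.zip")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
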
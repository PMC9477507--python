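"""Quantitative comparison machinery: RMSE, shell/tissue correlations,
metric-bias summaries, and the cross-phantom transfer experiment.

The transfer experiment is the simulation analogue of round-robin
cross-subject denoising: a model trained on one phantom ("subject") is
applied to independently generated phantoms, and the resulting diffusion
metric maps denoised with models from different training phantoms are
correlated against each other.  High cross-model correlation means the
choice of training dataset has negligible influence on the denoised data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cnn, dti, noise, phantom
from .io import DWIDataset, VoxelMatrix, to_voxel_matrix

__all__ = [
    "EvalReport",
    "rmse",
    "shell_tissue_correlation",
    "metric_bias_report",
    "transfer_experiment",
]

MIN_STRATUM_SAMPLES = 10


@dataclass
class EvalReport:
    """Nested-dict report with lossless JSON/CSV round-trips."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"sections": self.sections, "provenance": self.provenance}
        path.write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=_jsonify)
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        payload = json.loads(Path(path).read_text())
        return cls(sections=payload["sections"], provenance=payload["provenance"])

    def to_csv(self, path: str | Path) -> Path:
        """Flatten scalar leaves to a (section, key, value) table."""
        rows = []

        def walk(prefix, node):
            if isinstance(node, dict):
                for k in sorted(node):
                    walk(prefix + [str(k)], node[k])
            elif isinstance(node, (int, float, str)):
                rows.append({"key": "/".join(prefix), "value": node})

        walk([], self.sections)
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def rmse(
    a: DWIDataset,
    b: DWIDataset,
    mask: np.ndarray | None = None,
    shell: float | None = None,
) -> float:
    """Root-mean-square difference over masked voxels and selected volumes."""
    if a.data.shape != b.data.shape:
        raise ValueError("datasets have different shapes")
    m = a.mask & b.mask if mask is None else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty (disjoint) mask")
    vol = a.protocol.volume_indices(shell)
    diff = a.data[m][:, vol].astype(np.float64) - b.data[m][:, vol]
    return float(np.sqrt(np.mean(diff**2)))


def shell_tissue_correlation(
    a: DWIDataset,
    b: DWIDataset,
    mask: np.ndarray,
    labels: np.ndarray,
    shell: float | None = None,
    pooled: bool = True,
) -> dict[int, float]:
    """Pearson r between two datasets per tissue on one shell.

    ``pooled`` (default): volumes of the shell are pooled after removing
    per-volume means from each dataset, so global intensity offsets do not
    inflate r.  With ``pooled=False``, r is computed per volume and
    averaged.  Strata with fewer than 10 voxels are omitted with a warning.
    """
    vol = a.protocol.volume_indices(shell)
    out: dict[int, float] = {}
    for lab in np.unique(labels[labels > 0]):
        vox = (labels == lab) & mask
        if vox.sum() < MIN_STRATUM_SAMPLES:
            warnings.warn(
                f"tissue {lab}: fewer than {MIN_STRATUM_SAMPLES} voxels; "
                "stratum omitted",
                stacklevel=2,
            )
            continue
        xa = a.data[vox][:, vol].astype(np.float64)
        xb = b.data[vox][:, vol].astype(np.float64)
        if pooled:
            # tolerance guards strata that are constant up to float rounding
            tol_a = 1e-10 * max(float(np.abs(xa).max()), 1e-300)
            tol_b = 1e-10 * max(float(np.abs(xb).max()), 1e-300)
            xa = (xa - xa.mean(axis=0, keepdims=True)).ravel()
            xb = (xb - xb.mean(axis=0, keepdims=True)).ravel()
            if xa.std() <= tol_a or xb.std() <= tol_b:
                warnings.warn(
                    f"tissue {lab}: zero within-tissue variance; stratum "
                    "omitted",
                    stacklevel=2,
                )
                continue
            r = stats.pearsonr(xa, xb).statistic
        else:
            tol_a = 1e-10 * max(float(np.abs(xa).max()), 1e-300)
            tol_b = 1e-10 * max(float(np.abs(xb).max()), 1e-300)
            rs = [
                stats.pearsonr(xa[:, j], xb[:, j]).statistic
                for j in range(xa.shape[1])
                if xa[:, j].std() > tol_a and xb[:, j].std() > tol_b
            ]
            if not rs:
                warnings.warn(
                    f"tissue {lab}: zero within-tissue variance; stratum "
                    "omitted",
                    stacklevel=2,
                )
                continue
            r = float(np.mean(rs))
        out[int(lab)] = float(r)
    return out


def metric_bias_report(
    fits: dict[str, dti.TensorFit],
    gt_fit: dti.TensorFit,
    labels: np.ndarray,
    n_bins: int = 100,
) -> dict:
    """Per-tissue mean/SD bias and histograms for FA and MD vs ground truth."""
    gt_maps = dti.metric_maps(gt_fit)
    report: dict = {"histogram_bins": n_bins, "datasets": {}}
    for name, fit in fits.items():
        maps = dti.metric_maps(fit)
        entry: dict = {}
        for metric in ("FA", "MD"):
            entry[metric] = {}
            pooled = np.concatenate(
                [maps[metric][fit.mask], gt_maps[metric][gt_fit.mask]]
            )
            lo, hi = float(pooled.min()), float(pooled.max())
            edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
            for lab in np.unique(labels[labels > 0]):
                vox = (labels == lab) & fit.mask & gt_fit.mask
                diff = maps[metric][vox] - gt_maps[metric][vox]
                hist, _ = np.histogram(maps[metric][vox], bins=edges)
                entry[metric][int(lab)] = {
                    "bias_mean": float(diff.mean()),
                    "bias_sd": float(diff.std()),
                    "hist_counts": hist.tolist(),
                    "hist_edges": [float(edges[0]), float(edges[-1])],
                }
        report["datasets"][name] = entry
    return report


# ---------------------------------------------------------------------------
# cross-phantom transfer


def _phantom_pair(
    seed: int,
    proto,
    shape,
    snr: float,
    combine: str,
    coil_seed: int,
    train_draw: bool = True,
):
    """Phantom + noise-free combined reference + one corrupted dataset."""
    ph = phantom.make_phantom(shape=shape, seed=seed)
    gt = phantom.simulate_noise_free(ph, proto)
    coil = noise.make_coil_model(shape, sigma=1.0, seed=coil_seed)
    sigma = noise.sigma_for_snr(gt, ph.labels, snr, combine, coil)
    coil = coil.with_sigma(sigma)
    ref = noise.combine_noise_free(gt, coil, combine)
    draw_seed = seed * 2 + (0 if train_draw else 1)
    noisy = noise.corrupt(gt, coil, combine, seed=draw_seed)
    return ph, ref, noisy


def transfer_experiment(
    seeds: list[int],
    snr: float,
    cfg: cnn.DenoiserConfig,
    shape: tuple[int, int, int] = (64, 64, 4),
    combine: str = "sos",
    train_voxels: int | None = None,
    protocol=None,
) -> EvalReport:
    """Round-robin transfer across phantoms.

    For every phantom seed a model is trained on that phantom's noisy/
    reference pair; each model is then applied to every *other* phantom.
    The report contains, per ordered (train, test) pair, the RMSE of the
    noisy and denoised data against the combined noise-free reference, and,
    per test phantom, the Pearson correlation between FA/MD maps denoised
    with models from two different training phantoms, alongside the
    noisy-vs-ground-truth FA/MD correlation for reference.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 phantom seeds for a transfer test")
    proto = protocol if protocol is not None else phantom.make_protocol(seed=0)
    phantoms = {}
    for s in seeds:
        ph, ref, noisy = _phantom_pair(s, proto, shape, snr, combine,
                                       coil_seed=1000 + s)
        phantoms[s] = {"phantom": ph, "ref": ref, "noisy": noisy}

    rng = np.random.default_rng(cfg.seed)
    models = {}
    for s in seeds:
        entry = phantoms[s]
        vm_noisy = to_voxel_matrix(entry["noisy"])
        vm_ref = to_voxel_matrix(entry["ref"])
        if train_voxels is not None and train_voxels < vm_noisy.V:
            pick = rng.choice(vm_noisy.V, size=train_voxels, replace=False)
            vm_noisy = VoxelMatrix(vm_noisy.values[pick], vm_noisy.index[pick])
            vm_ref = VoxelMatrix(vm_ref.values[pick], vm_ref.index[pick])
        models[s] = cnn.train(vm_noisy, vm_ref, cfg, protocol=proto)

    pair_rows = []
    denoised: dict[tuple[int, int], DWIDataset] = {}
    for s_train in seeds:
        for s_test in seeds:
            if s_test == s_train:
                continue
            entry = phantoms[s_test]
            dn = cnn.denoise(models[s_train], entry["noisy"])
            denoised[(s_train, s_test)] = dn
            pair_rows.append(
                {
                    "train_seed": s_train,
                    "test_seed": s_test,
                    "rmse_noisy": rmse(entry["noisy"], entry["ref"]),
                    "rmse_denoised": rmse(dn, entry["ref"]),
                }
            )

    metric_corr: dict = {}
    for s_test in seeds:
        others = [s for s in seeds if s != s_test]
        if len(others) < 2:
            continue
        entry = phantoms[s_test]
        fits = {
            s_train: dti.fit_dti_wls(denoised[(s_train, s_test)])
            for s_train in others
        }
        gt_fit = dti.fit_dti_wls(entry["ref"])
        noisy_fit = dti.fit_dti_wls(entry["noisy"])
        mask = entry["ref"].mask
        pair = (others[0], others[1])
        metric_corr[s_test] = {}
        for metric in ("FA", "MD"):
            m_a = dti.metric_maps(fits[pair[0]])[metric][mask]
            m_b = dti.metric_maps(fits[pair[1]])[metric][mask]
            m_gt = dti.metric_maps(gt_fit)[metric][mask]
            m_noisy = dti.metric_maps(noisy_fit)[metric][mask]
            metric_corr[s_test][metric] = {
                "cross_model_r": float(stats.pearsonr(m_a, m_b).statistic),
                "noisy_vs_gt_r": float(stats.pearsonr(m_noisy, m_gt).statistic),
            }

    return EvalReport(
        sections={
            "pairs": pair_rows,
            "metric_correlations": metric_corr,
        },
        provenance={
            "seeds": list(seeds),
            "snr": snr,
            "combine": combine,
            "shape": list(shape),
            "epochs": cfg.epochs,
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "train_voxels": train_voxels,
        },
    )
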
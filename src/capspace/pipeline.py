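"""End-to-end orchestration of the memory- and response-stage analyses.

``run_all`` executes: stimulus generation -> model training (U-CapsNet +
controls) -> feature extraction -> hand features -> RDMs -> RSA against a
synthetic cohort (with noise ceilings, permutation tests and condition
splits by memory load / delay / probe truth) -> voxelwise encoding
(memory stage, and response stage with stimulus+probe concatenation) ->
RDM-level mediation -> representational-change analysis -> behavior
correlation, and writes a JSON + TSV report.

Every stochastic step derives its generator from the master seed through
named substreams, so identical configs give identical reports.  The
expensive training/extraction stage is cached on disk keyed by a hash of
the fields that determine it; re-running any later stage from the cache
reproduces the full-run outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import capsnet, control_models, encoding, mediation, repchange, rsa
from . import spatial_features as sf
from . import stimuli, synthetic_brain

log = logging.getLogger("capspace")


@dataclass
class RunConfig:
    seed: int = 0
    epochs: int = 30
    control_epochs: int = 30
    n_train_per_class: int = 100
    tiny_models: bool = False
    n_subjects: int = 8
    n_voxels: int = 60
    lam: float = 0.8
    noise_sd: float = 0.3
    n_perm: int = 200
    out_dir: str = "capspace_run"
    batch_size: int | None = 100
    stages: tuple[str, ...] = (
        "rsa_models",
        "rsa_brain",
        "encoding",
        "mediation",
        "repchange",
        "behavior",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child generator of the master seed."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def _feature_cache_key(cfg: RunConfig) -> str:
    payload = json.dumps(
        [cfg.seed, cfg.epochs, cfg.control_epochs, cfg.n_train_per_class,
         cfg.tiny_models, cfg.batch_size],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_model_features(cfg: RunConfig, out: Path) -> dict[str, np.ndarray]:
    """Train all models and extract stimulus/probe features (cached)."""
    cache = out / f"features_{_feature_cache_key(cfg)}.npz"
    if cache.exists():
        log.info("loading cached features from %s", cache)
        with np.load(cache) as z:
            return {k: z[k] for k in z.files}
    paradigm = stimuli.build_paradigm(cfg.seed)
    stims, probes = stimuli.paradigm_images(paradigm)
    train_imgs = stimuli.build_training_set(cfg.n_train_per_class, seed=cfg.seed + 1)
    enc_cfg = capsnet.tiny_config() if cfg.tiny_models else capsnet.EncoderConfig()
    log.info("training U-CapsNet (%d epochs)", cfg.epochs)
    model = capsnet.train(
        train_imgs, epochs=cfg.epochs, seed=cfg.seed, config=enc_cfg,
        batch_size=cfg.batch_size,
    )
    feats: dict[str, np.ndarray] = {}
    for tag, imgs in (("stim", stims), ("probe", probes)):
        layer_feats = capsnet.extract_features(model, imgs)
        for layer, F in layer_feats.items():
            feats[f"{tag}_{layer}"] = F
    # control models
    labels = control_models.labels_from_images(train_imgs)
    basis = sf.fit_image_pca(train_imgs, n_components=0.99)
    feats["stim_PCA"] = basis.transform(stims)
    feats["probe_PCA"] = basis.transform(probes)
    vae_cfg = (
        control_models.tiny_vae_config() if cfg.tiny_models
        else control_models.VAEConfig()
    )
    log.info("training control models (%d epochs)", cfg.control_epochs)
    vae = control_models.train_vae(
        train_imgs, config=vae_cfg, seed=cfg.seed, epochs=cfg.control_epochs,
        batch_size=cfg.batch_size,
    )
    feats["stim_VAE"] = vae.features(stims)
    feats["probe_VAE"] = vae.features(probes)
    sff = control_models.train_sff_cnn(
        train_imgs, labels, seed=cfg.seed, epochs=cfg.control_epochs,
        conv=control_models.ConvStackConfig(channels=(8, 8, 8)) if cfg.tiny_models else None,
        batch_size=cfg.batch_size,
    )
    feats["stim_SFF_CNN"] = sff.features(stims)
    feats["probe_SFF_CNN"] = sff.features(probes)
    scaps = control_models.train_s_capsnet(
        train_imgs, labels, encoder_config=enc_cfg, seed=cfg.seed,
        epochs=cfg.control_epochs, batch_size=cfg.batch_size,
    )
    feats["stim_S_CapsNet"] = scaps.features(stims)
    feats["probe_S_CapsNet"] = scaps.features(probes)
    # hand features of the stimulus arrays
    table = sf.feature_table(stims, sf.fit_image_pca(train_imgs, 0.95))
    feats["stim_SLF"] = table[sf.SLF_COLUMNS].to_numpy(dtype=float)
    feats["stim_SDF"] = table[sf.SDF_COLUMNS].to_numpy(dtype=float)
    feats["stim_VFNSFN"] = table[sf.VFNSFN_COLUMNS].to_numpy(dtype=float)
    feats["stim_pixels"] = np.stack([im.flat() for im in stims])
    feats["probe_pixels"] = np.stack([im.flat() for im in probes])
    feats["set_size"] = np.array([t.set_size for t in paradigm.trials], dtype=float)
    feats["delay_s"] = np.array([t.delay_s for t in paradigm.trials], dtype=float)
    feats["truth"] = np.array(
        [t.truth == stimuli.Truth.TRUE_POSITIVE for t in paradigm.trials],
        dtype=float,
    )
    np.savez_compressed(cache, **feats)
    return feats


MODEL_LAYERS = ("L1", "L2", "L2N", "L3")
CONTROLS = ("pixels", "PCA", "VAE", "SFF_CNN", "S_CapsNet")
HAND = ("SLF", "SDF", "VFNSFN")


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict()}
    feats = compute_model_features(cfg, out)
    n_cond = feats["stim_L3"].shape[0]
    ids = tuple(range(n_cond))

    def rdm_of(key: str) -> rsa.RDM:
        return rsa.compute_rdm(feats[key], "euclidean", condition_ids=ids)

    stim_rdms = {
        name: rdm_of(f"stim_{name}")
        for name in (*MODEL_LAYERS, *CONTROLS, *HAND)
    }

    if "rsa_models" in cfg.stages:
        rows = []
        rng = _substream(cfg.seed, "rsa_models")
        for model_name in (*MODEL_LAYERS, *CONTROLS):
            for other in (*HAND, "pixels", "PCA"):
                if model_name == other:
                    continue
                method = "spearman" if other in HAND else "pearson"
                res = rsa.permutation_test(
                    stim_rdms[model_name], stim_rdms[other],
                    method=method, n_perm=cfg.n_perm, seed=rng,
                )
                rows.append(
                    {"model": model_name, "reference": other,
                     "method": method, "r": res.r, "p_perm": res.p_perm,
                     "exceeds_null_max": res.exceeds_null_max}
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "rsa_models.tsv", sep="\t", index=False)
        report["rsa_models"] = df.to_dict("records")

    # synthetic cohort with planted geometry: capsule-layer geometry in
    # associative regions, capsule-norm geometry in dorsal-stream regions
    planted_sources = {
        "frontal": "stim_L2", "ventral": "stim_L2", "hippocampus": "stim_L2",
        "dorsal": "stim_L2N", "early_visual": "stim_L2N",
    }
    target_rdms = {
        r: rsa.compute_rdm(feats[src], "correlation_distance", condition_ids=ids)
        for r, src in planted_sources.items()
    }
    subjects, accuracies, manifest = synthetic_brain.simulate_cohort(
        cfg.n_subjects, target_rdms, per_region_lambda=cfg.lam,
        n_voxels=cfg.n_voxels, noise_sd=cfg.noise_sd, seed=cfg.seed + 17,
    )
    report["cohort_manifest"] = {
        k: v for k, v in manifest.items() if k != "similarities"
    }
    all_subject_rdms = [
        synthetic_brain.subject_rdms(s, condition_ids=ids) for s in subjects
    ]

    splits = {
        "all": np.arange(n_cond),
        "load_low": np.flatnonzero(feats["set_size"] <= 3),
        "load_high": np.flatnonzero(feats["set_size"] >= 5),
        "delay_short": np.flatnonzero(feats["delay_s"] == 1.5),
        "delay_long": np.flatnonzero(feats["delay_s"] == 4.5),
        "true_positive": np.flatnonzero(feats["truth"] == 1),
        "true_negative": np.flatnonzero(feats["truth"] == 0),
    }

    if "rsa_brain" in cfg.stages:
        rng = _substream(cfg.seed, "rsa_brain")
        rows = []
        for region in target_rdms:
            ceiling = rsa.noise_ceiling(
                [sr[region] for sr in all_subject_rdms], method="pearson"
            )
            for layer in MODEL_LAYERS:
                for split_name, idx in splits.items():
                    model_sub = stim_rdms[layer].subset(idx)
                    rs = []
                    for sr in all_subject_rdms:
                        rs.append(
                            rsa.compare_rdms(
                                model_sub, sr[region].subset(idx), "pearson"
                            ).r
                        )
                    row = {
                        "stage": "memory", "region": region, "model": layer,
                        "split": split_name, "mean_r": float(np.mean(rs)),
                    }
                    if split_name == "all":
                        res = rsa.permutation_test(
                            stim_rdms[layer], all_subject_rdms[0][region],
                            method="pearson", n_perm=cfg.n_perm, seed=rng,
                        )
                        row.update(
                            p_perm_sub0=res.p_perm,
                            noise_ceiling_lower=ceiling.lower,
                            noise_ceiling_upper=ceiling.upper,
                        )
                    rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / "rsa_brain.tsv", sep="\t", index=False)
        report["rsa_brain"] = df.to_dict("records")

    if "encoding" in cfg.stages:
        rows = []
        for layer in (*MODEL_LAYERS, "PCA", "VAE", "SFF_CNN", "S_CapsNet"):
            mem_design = encoding.reduce_features(
                feats[f"stim_{layer}"], 0.99, source_layer=layer, stage="memory"
            )
            resp_design = encoding.reduce_features(
                encoding.concat_stage_features(
                    feats[f"stim_{layer}"], feats[f"probe_{layer}"]
                ),
                0.99, source_layer=layer, stage="response",
            )
            for stage, design in (("memory", mem_design), ("response", resp_design)):
                for region in target_rdms:
                    accs = [
                        encoding.loocv_encode(design, s.regions[region])
                        .per_region_mean["all"]
                        for s in subjects
                    ]
                    rows.append(
                        {"stage": stage, "model": layer, "region": region,
                         "n_components": design.n_components,
                         "mean_accuracy": float(np.mean(accs))}
                    )
        df = pd.DataFrame(rows)
        df.to_csv(out / "encoding.tsv", sep="\t", index=False)
        report["encoding"] = df.to_dict("records")

    # mean brain RDM: averaged across regions, then subjects
    brain_tris = np.mean(
        [
            np.mean([sr[r].triangle() for r in target_rdms], axis=0)
            for sr in all_subject_rdms
        ],
        axis=0,
    )

    if "mediation" in cfg.stages:
        med_results = {}
        for iv_name, med_name in (("SLF", "L2"), ("SDF", "L2"), ("VFNSFN", "L2N")):
            res = mediation.fit_mediation(
                stim_rdms[iv_name].triangle(),
                stim_rdms[med_name].triangle(),
                brain_tris,
            )
            med_results[f"{iv_name}->{med_name}->brain"] = asdict(res)
        report["mediation"] = med_results
        pd.DataFrame(med_results).T.to_csv(out / "mediation.tsv", sep="\t")

    if "repchange" in cfg.stages:
        model_diff = repchange.change_rdm(
            stim_rdms["L2"], stim_rdms["L2N"], "L2", "L2N"
        )
        pairs = [("dorsal", "frontal"), ("dorsal", "ventral"),
                 ("early_visual", "hippocampus")]
        per_subject_pairs = []
        for sr in all_subject_rdms:
            per_subject_pairs.append(
                {
                    (a, b): repchange.change_rdm(sr[a], sr[b], a, b)
                    for a, b in pairs
                }
            )
        df, agg = repchange.repchange_rsa(
            model_diff, per_subject_pairs, n_perm=cfg.n_perm,
            seed=cfg.seed + 23,
        )
        df.to_csv(out / "repchange.tsv", sep="\t", index=False)
        report["repchange"] = agg.to_dict("records")

    if "behavior" in cfg.stages:
        sims = np.array(
            [
                np.mean(
                    [
                        rsa.compare_rdms(stim_rdms["L2"], sr[r], "pearson").r
                        for r in target_rdms
                    ]
                )
                for sr in all_subject_rdms
            ]
        )
        df = rsa.behavior_correlation(sims, accuracies)
        per_roi = rsa.behavior_correlation(
            np.array(
                [
                    [
                        rsa.compare_rdms(stim_rdms["L2"], sr[r], "pearson").r
                        for r in target_rdms
                    ]
                    for sr in all_subject_rdms
                ]
            ),
            accuracies,
            roi_labels=list(target_rdms),
        )
        behav = pd.concat([df, per_roi], ignore_index=True)
        behav.to_csv(out / "behavior.tsv", sep="\t", index=False)
        report["behavior"] = behav.to_dict("records")

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
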
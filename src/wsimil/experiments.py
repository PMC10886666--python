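"""Prepackaged desk-scale experiments over the synthetic cohorts.

These functions reproduce, at reduced problem sizes, the study's main
computations: the encoder compression sweep on rendered slides, MISL
parameter recovery with cut-off stratification, and the comparison of
patch-size variants when the risk signal is carried at coarse scale.
"""

from __future__ import annotations

import numpy as np

from .features import EncoderConfig, IdentityEncoder, pairing_accuracy, sample_pairs
from .mil import evaluate_classification, train_mil
from .misl import concordance_index, train_misl
from .survstats import best_cutoff
from .synthetic import (
    CohortSpec,
    generate_cohort,
    generate_feature_bags,
    generate_tissue_image,
    oracle_c_index,
)
from .tiling import manifest_frame, patch_image, tile_wsi

#: encoder settings of the desk-scale compression sweep
SWEEP_ENCODER = dict(input_px=32, strides=(2, 2, 1, 1),
                     channels=(12, 24, 48, 64), batch_size=128,
                     epochs=50, lr=3e-3)


def pairing_dataset(seed: int, n_wsi: int = 36, image_size_px: int = 2048,
                    tissue_fraction: float = 0.55,
                    n_pairs_per_wsi: int | str = "all"):
    """Render a slide cohort and assemble the pair dataset for the pretext
    task: (train patches, val patches, identity labels)."""
    spec = CohortSpec(n_patients=n_wsi, image_size_px=image_size_px,
                      rng_seed=seed, tissue_fraction=tissue_fraction)
    patients, _ = generate_cohort(spec)
    records, images = [], {}
    for p in patients:
        img, mask = generate_tissue_image(spec, p)
        records.extend(tile_wsi(img, mask, wsi_id=p.patient_id))
        images[p.patient_id] = img
    manifest = manifest_frame(records)
    by_id = {r.patch_id: r for r in records}
    wsi_index = {w: i for i, w in enumerate(sorted(images))}
    pairs = sample_pairs(manifest, n_pairs_per_wsi, seed=seed)

    def img_of(pid):
        rec = by_id[pid]
        return patch_image(images[rec.wsi_id], rec)

    X_train = np.stack([img_of(p.train_patch_id) for p in pairs])
    X_val = np.stack([img_of(p.val_patch_id) for p in pairs])
    y = np.array([wsi_index[p.wsi_id] for p in pairs])
    return X_train, X_val, y


def pairing_accuracy_for_width(X_train, X_val, y, width: int, seed: int,
                               compression_mode: str = "conv2d",
                               **overrides) -> float:
    """Train the identity encoder at one compression width; return the
    validation pairing accuracy."""
    cfg = EncoderConfig(width=width, compression_mode=compression_mode,
                        seed=seed, **{**SWEEP_ENCODER, **overrides})
    encoder = IdentityEncoder(cfg).fit(X_train, y)
    return pairing_accuracy(encoder, X_val, y)


def compression_sweep(seed: int, widths=(1536, 64, 32), **dataset_kwargs) -> dict:
    """The Fig-3B-style sweep at one seed: width -> pairing accuracy."""
    X_train, X_val, y = pairing_dataset(seed, **dataset_kwargs)
    return {w: pairing_accuracy_for_width(X_train, X_val, y, w, seed)
            for w in widths}


def _permute_survival(bags, seed: int):
    """Shuffle (time, event) pairs across patients, breaking any feature
    association while preserving the marginal survival distribution."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(bags))
    out = []
    for bag, j in zip(bags, perm):
        src = bags[j]
        clone = type(bag)(bag.patient_id, bag.instances, bag.cluster_labels,
                          label=bag.label, time_days=src.time_days,
                          event=src.event)
        out.append(clone)
    return out


def misl_recovery(seed: int, n_patients: int = 200, variant: str = "multires",
                  permute: bool = False, k: int = 3,
                  max_epochs: int = 150, patience: int = 30,
                  **misl_params) -> dict:
    """Train MISL on a planted-signal cohort; report out-of-fold concordance,
    the oracle ceiling, and the optimal-cut-off one-sided log-rank p."""
    spec = CohortSpec(n_patients=n_patients, rng_seed=seed)
    patients, _ = generate_cohort(spec)
    bags = generate_feature_bags(spec, patients, variant=variant)
    if permute:
        bags = _permute_survival(bags, seed)
    risk_df, fold_df = train_misl(bags, k=k, seed=seed, max_epochs=max_epochs,
                                  patience=patience, **misl_params)
    c = concordance_index(risk_df["risk"], risk_df["time_days"], risk_df["event"])
    out = {"c_index": float(c), "oracle_c_index": float(oracle_c_index(patients)),
           "fold_c": fold_df["c_index"].tolist()}
    try:
        cut = best_cutoff(risk_df["risk"].to_numpy(),
                          risk_df["time_days"].to_numpy(),
                          risk_df["event"].to_numpy())
        out["cutoff"] = cut["cutoff"]
        out["logrank_p"] = cut["p"]
    except ValueError:
        out["logrank_p"] = float("nan")
    return out


def variant_comparison(seed: int, n_patients: int = 50,
                       variants=("multires", "1024", "256"),
                       max_epochs: int = 100, patience: int = 25) -> dict:
    """Out-of-fold MISL concordance per patch-size variant on one cohort
    whose risk signal is carried predominantly at coarse scale."""
    spec = CohortSpec(n_patients=n_patients, rng_seed=seed)
    patients, _ = generate_cohort(spec)
    out = {}
    for variant in variants:
        bags = generate_feature_bags(spec, patients, variant=variant)
        risk_df, _ = train_misl(bags, k=3, seed=seed, max_epochs=max_epochs,
                                patience=patience)
        out[variant] = float(concordance_index(
            risk_df["risk"], risk_df["time_days"], risk_df["event"]))
    return out


def mil_relapse_run(seed: int, n_patients: int = 100, horizon_days: float = 730,
                    variant: str = "multires", signal_scale: float = 3.0,
                    hazard_coefficient: float | None = None,
                    max_epochs: int = 300, patience: int = 60) -> dict:
    """Cross-validated MIL relapse classification on a planted-signal cohort."""
    cohort_kwargs = {}
    if hazard_coefficient is not None:
        cohort_kwargs["hazard_coefficient"] = hazard_coefficient
    spec = CohortSpec(n_patients=n_patients, rng_seed=seed, **cohort_kwargs)
    patients, _ = generate_cohort(spec)
    bags = generate_feature_bags(spec, patients, variant=variant,
                                 signal_scale=signal_scale)
    pred_df, fold_df = train_mil(bags, horizon_days=horizon_days, k=5,
                                 seed=seed, max_epochs=max_epochs,
                                 patience=patience)
    metrics = evaluate_classification(pred_df["p"], pred_df["label"])
    metrics["n_labeled"] = int(len(pred_df))
    return metrics
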
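"""End-to-end experiment helpers shared by the CLI, tests and scripts.

This module wires the pieces together: phantom datasets, shearlet
transforms of normalized images, ensemble training for image- and
sinogram-domain wavefront extraction, and MF-score evaluation (pooled over
a test set, or averaged per image).

The ``scaled_*`` constructors encode the package's desk-scale study
conditions: 8 orientation bins on 64 x 64 images, a 2-scale shearlet
system (17 slices), 300 training phantoms with 10 patches each, and a
compact classifier (channels 8/16/32/32, dense width 256, 10 epochs).
Full-scale defaults elsewhere keep the reference conditions (180 bins,
4 scales / 49 slices, 10000 training images, channels 32/64/128/256,
dense width 1024).
"""

from __future__ import annotations

import numpy as np

from .classifier import (
    PATCH_SIZE,
    ClassifierEnsemble,
    ClassifierSpec,
    ConstantClassifier,
    TrainConfig,
    build_training_set,
    normalize_image,
    predict_wavefront_set,
    train_classifier,
)
from .errors import TrainingError
from .phantoms import Phantom, PhantomConfig, sample_head_phantom
from .shearlets import ShearletConfig, ShearletSystem, build_shearlet_system, shearlet_transform
from .tomo import (
    Sinogram,
    SinogramGeometry,
    embed_sinogram_periodic,
    fold_extended_rows,
    ray_transform,
    sinogram_wavefront_truth,
)
from .wavefront import (
    DigitalWavefrontSet,
    MatchTolerance,
    bin_match_counts,
    fscore_from_counts,
    mf_score,
)

__all__ = [
    "scaled_phantom_config",
    "scaled_system",
    "scaled_classifier_spec",
    "scaled_train_config",
    "generate_phantoms",
    "phantom_volume",
    "train_ensemble",
    "pooled_mf_score",
    "evaluate_image_mf",
    "sinogram_square_dataset",
    "predict_sinogram_wavefront",
    "evaluate_sinogram_mf",
    "run_desk_scale_study",
]


# -- desk-scale study conditions -------------------------------------------

SCALED_IMAGE_SIZE = 64
SCALED_N_SCALES = 2
SCALED_N_ORIENTATIONS = 8
SCALED_N_TRAIN_PHANTOMS = 300
SCALED_N_EVAL_PHANTOMS = 20


def scaled_phantom_config(image_size: int = SCALED_IMAGE_SIZE) -> PhantomConfig:
    return PhantomConfig(image_size=image_size, n_small=(3, 7),
                         n_orientations=SCALED_N_ORIENTATIONS, supersample=4)


def scaled_system(image_size: int = SCALED_IMAGE_SIZE) -> ShearletSystem:
    return build_shearlet_system(ShearletConfig(image_size, n_scales=SCALED_N_SCALES))


def scaled_classifier_spec() -> ClassifierSpec:
    return ClassifierSpec(conv_channels=(8, 16, 32, 32), dense_units=256)


def scaled_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=10, batch_size=64, learning_rate=1e-3, seed=seed,
                       n_train=SCALED_N_TRAIN_PHANTOMS, n_val=SCALED_N_EVAL_PHANTOMS,
                       n_test=SCALED_N_EVAL_PHANTOMS)


# -- datasets ---------------------------------------------------------------


def generate_phantoms(config: PhantomConfig, n: int, seed: int) -> list[Phantom]:
    """n phantoms with per-phantom seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [sample_head_phantom(config, rng_seed=int(s.generate_state(1)[0] % (2 ** 31)))
            for s in ss.spawn(n)]


def phantom_volume(phantom: Phantom, system: ShearletSystem):
    """Shearlet volume of the min-max normalized phantom image."""
    return shearlet_transform(normalize_image(phantom.image), system)


# -- training ---------------------------------------------------------------


def train_ensemble(
    volumes,
    truths,
    n_orientations: int,
    spec: ClassifierSpec,
    trainconfig: TrainConfig,
    threshold: float = 0.5,
    verbose: bool = False,
) -> ClassifierEnsemble:
    """Train the N + 1 binary classifiers on a shared volume/truth pool."""
    rng = np.random.default_rng(trainconfig.seed)
    models = []
    input_shape = (volumes[0].data.shape[0], PATCH_SIZE, PATCH_SIZE)
    degenerate = []
    tasks = [f"orientation:{b}" for b in range(n_orientations)] + ["edge"]
    for task in tasks:
        try:
            patchset = build_training_set(volumes, truths, task, trainconfig, rng)
        except TrainingError:
            # direction never (or almost never) occurs in this domain: a
            # constant-zero classifier is the correct degenerate model
            if task == "edge":
                raise
            models.append(ConstantClassifier(0.0, input_shape))
            degenerate.append(task)
            if verbose:
                print(f"  {task}: no positives available, constant-zero model")
            continue
        model, history = train_classifier(patchset, spec, trainconfig)
        if verbose and history:
            last = history[-1]
            print(f"  {task}: loss={last['loss']:.4f} val_f={last.get('val_f', float('nan')):.3f}")
        models.append(model)
    return ClassifierEnsemble(
        orientation_models=models[:-1],
        edge_model=models[-1],
        n_orientations=n_orientations,
        threshold=threshold,
        metadata={"seed": trainconfig.seed, "n_images": len(volumes),
                  "degenerate_tasks": degenerate},
    )


# -- evaluation -------------------------------------------------------------


def pooled_mf_score(preds, truths, tol: MatchTolerance = MatchTolerance()) -> float:
    """MF-score with per-bin counts pooled over a set of image pairs."""
    n_orientations = truths[0].n_orientations
    bins = set()
    for wf in list(preds) + list(truths):
        bins |= wf.bins_present()
    if not bins:
        return 1.0
    scores = []
    for b in sorted(bins):
        mp = npred = mr = ntruth = 0
        for pred, truth in zip(preds, truths):
            a, b_, c, d = bin_match_counts(pred, truth, b, tol)
            mp, npred, mr, ntruth = mp + a, npred + b_, mr + c, ntruth + d
        scores.append(fscore_from_counts(mp, npred, mr, ntruth))
    return float(np.mean(scores))


def evaluate_image_mf(
    phantoms,
    system: ShearletSystem,
    ensemble: ClassifierEnsemble,
    tol: MatchTolerance = MatchTolerance(),
    mode: str = "pooled",
) -> float:
    """MF-score of the extractor on held-out phantoms (interior truth only)."""
    preds, truths = [], []
    for ph in phantoms:
        preds.append(predict_wavefront_set(ph.image, system, ensemble))
        truths.append(_interior_truth(ph.truth))
    if mode == "pooled":
        return pooled_mf_score(preds, truths, tol)
    return float(np.mean([mf_score(p, t, tol) for p, t in zip(preds, truths)]))


def _interior_truth(truth: DigitalWavefrontSet, radius: int = 10) -> DigitalWavefrontSet:
    """Truth restricted to classifiable (interior) pixels."""
    rows, cols = truth.domain_shape
    out = DigitalWavefrontSet(truth.domain_shape, n_orientations=truth.n_orientations)
    for (r, c), bins in truth.elements.items():
        if radius <= r < rows - radius and radius <= c < cols - radius:
            for b in bins:
                out.add(r, c, b)
    return out


# -- sinogram-domain pipeline ----------------------------------------------


def sinogram_square_dataset(
    phantoms,
    geometry: SinogramGeometry,
    system: ShearletSystem,
    n_orientations: int,
):
    """Shearlet volumes of square-embedded sinograms with extended truths.

    Sinograms are extended to the system's square size via pi-periodicity
    (detector axis flipped every period) so that edge geometry is
    continuous across the seam; the canonical-relation truth is extended
    the same way.
    """
    size = system.image_size
    volumes, truths = [], []
    for ph in phantoms:
        sino = ray_transform(ph.image, geometry)
        square = embed_sinogram_periodic(sino, size)
        volumes.append(shearlet_transform(normalize_image(square), system))
        truth = sinogram_wavefront_truth(ph, geometry, n_orientations)
        truths.append(_extend_truth_periodic(truth, size))
    return volumes, truths


def _extend_truth_periodic(wf: DigitalWavefrontSet, size: int) -> DigitalWavefrontSet:
    n, n_det = wf.domain_shape
    n_or = wf.n_orientations
    out = DigitalWavefrontSet((size, n_det), n_orientations=n_or)
    for r in range(size):
        base, flip = r % n, (r // n) % 2 == 1
        for (rr, c), bins in wf.elements.items():
            if rr != base:
                continue
            for b in bins:
                if flip:
                    out.add(r, n_det - 1 - c, (n_or - 1 - b) % n_or)
                else:
                    out.add(r, c, b)
    return out


def predict_sinogram_wavefront(
    sinogram: Sinogram,
    system: ShearletSystem,
    ensemble: ClassifierEnsemble,
) -> DigitalWavefrontSet:
    """Wavefront set of a sinogram, folded back to the (angle, offset) grid."""
    square = embed_sinogram_periodic(sinogram, system.image_size)
    wf_ext = predict_wavefront_set(square, system, ensemble)
    return fold_extended_rows(wf_ext, sinogram.geometry)


def run_desk_scale_study(
    seed: int,
    n_train: int = SCALED_N_TRAIN_PHANTOMS,
    n_sino_train: int = 100,
    n_eval: int = 8,
    n_bench: int = 2,
    verbose: bool = False,
) -> dict:
    """Train and evaluate the desk-scale extractors end to end.

    Trains the image-domain ensemble on ``n_train`` phantoms and the
    sinogram-domain ensemble on low-dose (every 6 degrees) sinograms of the
    first ``n_sino_train`` of them, evaluates pooled MF-scores on held-out
    phantoms in both domains, and runs the four-route wavefront-recovery
    benchmark averaged over ``n_bench`` held-out phantoms.  Returns a dict
    with ``mf_image``, ``mf_sinogram`` and ``benchmark`` (method ->
    wavefront MSE).
    """
    import dataclasses

    from .recon import benchmark_wavefront_recovery
    from .tomo import sinogram_set_to_image_set

    cfg = scaled_phantom_config()
    system = scaled_system()
    phantoms = generate_phantoms(cfg, n_train, seed)
    volumes = [phantom_volume(p, system) for p in phantoms]
    truths = [p.truth for p in phantoms]
    tc = scaled_train_config(seed=seed)
    ensemble = train_ensemble(volumes, truths, cfg.n_orientations,
                              scaled_classifier_spec(), tc, verbose=verbose)
    eval_phantoms = generate_phantoms(cfg, n_eval, seed + 10_000)
    mf_image = evaluate_image_mf(eval_phantoms, system, ensemble)

    geometry = SinogramGeometry.parallel(cfg.image_size, angle_step_deg=6.0,
                                         n_det=cfg.image_size)
    sino_volumes, sino_truths = sinogram_square_dataset(
        phantoms[:n_sino_train], geometry, system, cfg.n_orientations)
    sino_ensemble = train_ensemble(sino_volumes, sino_truths, cfg.n_orientations,
                                   scaled_classifier_spec(),
                                   dataclasses.replace(tc, seed=seed + 1),
                                   verbose=verbose)
    mf_sino = evaluate_sinogram_mf(eval_phantoms[: max(4, n_eval // 2)], geometry,
                                   system, sino_ensemble)

    def sino_predictor(sino):
        wf = predict_sinogram_wavefront(sino, system, sino_ensemble)
        return sinogram_set_to_image_set(wf, geometry, cfg.n_orientations)

    def image_predictor(image):
        return predict_wavefront_set(image, system, ensemble)

    totals: dict[str, float] = {}
    for k in range(n_bench):
        rows = benchmark_wavefront_recovery(
            eval_phantoms[k], geometry, sino_predictor, image_predictor,
            noise_sigma=0.01, seed=seed + k)
        for row in rows:
            totals[row["method"]] = totals.get(row["method"], 0.0) + row["wavefront_mse"]
    benchmark = {m: v / n_bench for m, v in totals.items()}
    return {
        "mf_image": mf_image,
        "mf_sinogram": mf_sino,
        "benchmark": benchmark,
        "image_ensemble": ensemble,
        "sinogram_ensemble": sino_ensemble,
        "system": system,
        "geometry": geometry,
    }


def evaluate_sinogram_mf(
    phantoms,
    geometry: SinogramGeometry,
    system: ShearletSystem,
    ensemble: ClassifierEnsemble,
    tol: MatchTolerance = MatchTolerance(),
) -> float:
    """Pooled MF-score of sinogram wavefront extraction on held-out phantoms.

    Evaluated on the square-embedded domain (interior pixels), against the
    canonical-relation ground truth.
    """
    preds, truths = [], []
    for ph in phantoms:
        sino = ray_transform(ph.image, geometry)
        square = embed_sinogram_periodic(sino, system.image_size)
        preds.append(predict_wavefront_set(square, system, ensemble))
        truth = _extend_truth_periodic(
            sinogram_wavefront_truth(ph, geometry, ensemble.n_orientations),
            system.image_size,
        )
        truths.append(_interior_truth(truth))
    return pooled_mf_score(preds, truths, tol)
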
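"""Glue between the front-ends, the simulator and the classifier.

Turns respiratory cycles into stacked colour feature images for any of the
four time-frequency representations, and provides the labelled-array view
(images, labels, patients) that training and cross-validation consume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .audio_io import LABELS4, RespiratoryCycle
from .errors import ParameterError
from .tf_features import (
    CQTParams,
    FeatureImage,
    MelParams,
    STFTParams,
    TFRepresentation,
    cochleogram,
    cqt,
    design_gammatone_bank,
    log_mel_spectrogram,
    mfcc,
    stft,
    to_image,
)

FRONTENDS = ("stft", "mfcc", "logmel", "cqt", "cochleogram")


def compute_tf(x: np.ndarray, fs: float, frontend: str, **kwargs) -> TFRepresentation:
    """Compute one of the front-end representations with its package defaults.

    Keyword arguments override the corresponding parameter-object fields
    (e.g. ``N=256`` for the STFT window, ``M=40`` for the Mel bank, ``K=32``
    for the gammatone channel count).
    """
    if frontend == "stft":
        return stft(x, STFTParams(**kwargs), fs)
    if frontend in ("mfcc", "logmel"):
        stft_keys = {"window", "N", "J"}
        sp = STFTParams(**{k: v for k, v in kwargs.items() if k in stft_keys})
        mp = MelParams(
            fmax=fs / 2, **{k: v for k, v in kwargs.items() if k not in stft_keys}
        )
        fn = mfcc if frontend == "mfcc" else log_mel_spectrogram
        return fn(x, sp, mp, fs)
    if frontend == "cqt":
        return cqt(x, CQTParams(fmax=fs / 2, **kwargs), fs)
    if frontend == "cochleogram":
        frame_len = kwargs.pop("frame_len", 0.084)
        hop = kwargs.pop("hop", 0.042)
        bank = design_gammatone_bank(fs, **kwargs)
        return cochleogram(x, bank, frame_len=frame_len, hop=hop)
    raise ParameterError(f"unknown front-end {frontend!r}; expected one of {FRONTENDS}")


def featurize_cycles(
    cycles: list[RespiratoryCycle],
    frontend: str = "cochleogram",
    image_size: int = 64,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render every cycle to a colour feature image.

    Returns (images, labels4, patient_ids): a (n, image_size, image_size, 3)
    uint8 stack, integer 4-class labels in the canonical order
    (normal, crackle, wheeze, both), and the patient of each cycle.
    """
    images = np.empty((len(cycles), image_size, image_size, 3), dtype=np.uint8)
    labels = np.empty(len(cycles), dtype=np.int64)
    patients = np.empty(len(cycles), dtype=object)
    for i, cyc in enumerate(cycles):
        rep = compute_tf(cyc.samples, cyc.rate, frontend, **kwargs)
        images[i] = to_image(rep, image_size, image_size).pixels
        labels[i] = LABELS4.index(cyc.label4)
        patients[i] = cyc.patient_id
    return images, labels, patients


def binary_labels(labels4: np.ndarray, task: str) -> np.ndarray:
    """Reduce canonical 4-class integer labels to a binary target.

    ``wheeze_binary``: 1 for wheeze/both; ``crackle_binary``: 1 for
    crackle/both.
    """
    labels4 = np.asarray(labels4)
    if task == "wheeze_binary":
        return np.isin(labels4, (2, 3)).astype(int)
    if task == "crackle_binary":
        return np.isin(labels4, (1, 3)).astype(int)
    raise ParameterError(f"not a binary task: {task!r}")


def save_images(
    images: np.ndarray,
    labels: np.ndarray,
    patients: np.ndarray,
    out_dir,
    prefix: str = "cycle",
) -> pd.DataFrame:
    """Write PNG images plus a manifest CSV (cycle id, patient, label, path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab, pat) in enumerate(zip(images, labels, patients)):
        name = f"{prefix}_{i:05d}.png"
        Image.fromarray(img).save(out / name)
        rows.append(
            {
                "cycle_id": f"{prefix}_{i:05d}",
                "patient_id": pat,
                "label4": LABELS4[int(lab)],
                "image_path": name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "images_manifest.csv", index=False)
    return manifest
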
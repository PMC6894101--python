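"""Model persistence: a versioned .npz archive with the feature-space
sidecar, per-class weights and biases, and a config snapshot."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classify import LinearOvRModel
from .features import FeatureSpace

FORMAT_VERSION = 1

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]


def save_model(
    path: str | Path,
    model: LinearOvRModel,
    space: FeatureSpace,
    config: dict | None = None,
) -> None:
    np.savez_compressed(
        path,
        format_version=np.array(FORMAT_VERSION),
        classes=np.array(model.classes, dtype=object),
        coef=model.coef,
        intercept=model.intercept,
        C=np.array(model.C),
        vocabulary=np.array(space.vocabulary, dtype=object),
        vk=np.array(space.vk, dtype=object),
        idf=space.idf,
        df=np.array(json.dumps(space.df)),
        n_train_docs=np.array(space.n_train_docs),
        config=np.array(json.dumps(config or {}, sort_keys=True)),
    )


def load_model(path: str | Path) -> tuple[LinearOvRModel, FeatureSpace, dict]:
    with np.load(path, allow_pickle=True) as z:
        version = int(z["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        model = LinearOvRModel(
            classes=tuple(z["classes"].tolist()),
            coef=z["coef"],
            intercept=z["intercept"],
            C=float(z["C"]),
        )
        space = FeatureSpace(
            vocabulary=tuple(z["vocabulary"].tolist()),
            vk=tuple(z["vk"].tolist()),
            idf=z["idf"],
            df=json.loads(str(z["df"])),
            n_train_docs=int(z["n_train_docs"]),
        )
        config = json.loads(str(z["config"]))
    return model, space, config
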
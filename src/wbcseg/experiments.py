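"""Reference experiments at desk scale.

The full protocol (100 smear images at 256x256, 80/20 split, Adam at 1e-4
for 30 epochs) assumes clinical data and hours of compute.  These routines
reproduce every stage of the pipeline on synthetic scenes at sizes a
laptop CPU finishes in minutes: 50 scenes at 64x64, the smallest legal
model (2 encoder levels, 8 base channels), 30 epochs.  At one sixteenth
of the pixel budget and a fifth of the gradient steps, the protocol's
learning rate is rescaled accordingly (see docs/methods.md); the full-scale
defaults in TrainConfig are unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import metrics as mt
from . import model as M
from . import synthetic as S
from . import trainer as TR
from . import watershed as W

__all__ = ["DESK_IMAGE_SIZE", "DESK_N_SCENES", "desk_scenes",
           "desk_train_config", "desk_model_config", "run_desk_training",
           "DeskRun", "segment_scenes", "watershed_count_accuracy"]

DESK_IMAGE_SIZE = 64
DESK_N_SCENES = 50  # 40 train / 10 held out
DESK_LEARNING_RATE = 1e-2
DESK_BATCH_SIZE = 2


def desk_scenes(seed: int = 0, n: int = DESK_N_SCENES,
                size: int = DESK_IMAGE_SIZE) -> list[S.Scene]:
    spec = S.SceneSpec.for_size(size)
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [S.generate_scene(dataclasses.replace(spec, seed=int(s)))
            for s in seeds]


def desk_model_config(seed: int = 0) -> M.ModelConfig:
    """Smallest legal model: depth 2, 8 base channels."""
    return M.ModelConfig(depth=2, base_channels=8, seed=seed)


def desk_train_config(seed: int = 0) -> TR.TrainConfig:
    return TR.TrainConfig(learning_rate=DESK_LEARNING_RATE, epochs=30,
                          batch_size=DESK_BATCH_SIZE, seed=seed)


@dataclass
class DeskRun:
    model: M.UNetPlusPlus
    history: TR.TrainingHistory
    train_scenes: list
    val_scenes: list

    def val_dice_scores(self) -> list[float]:
        out = []
        for scene in self.val_scenes:
            prob = M.predict(self.model, scene.image.pixels)
            c = mt.confusion_counts(prob >= 0.5, scene.semantic.pixels)
            out.append(mt.dsm(c))
        return out


def run_desk_training(seed: int = 0) -> DeskRun:
    """Generate scenes, train the smallest model for 30 epochs, return all."""
    scenes = desk_scenes(seed)
    n_train = int(0.8 * len(scenes))
    pairs = [(sc.image.pixels, sc.semantic.pixels) for sc in scenes]
    net = M.build_model(desk_model_config(seed))
    net, history = TR.train(net, (pairs[:n_train], pairs[n_train:]),
                            desk_train_config(seed))
    return DeskRun(model=net, history=history,
                   train_scenes=scenes[:n_train], val_scenes=scenes[n_train:])


def segment_scenes(run: DeskRun,
                   params: W.WatershedParams | None = None):
    """Predict + watershed on the held-out scenes; returns label maps."""
    return [W.separate_cells(M.predict(run.model, sc.image.pixels), params)
            for sc in run.val_scenes]


def watershed_count_accuracy(n_scenes: int = 100, seed: int | None = None
                             ) -> tuple[int, int]:
    """Instance-count check: watershed on ideal probability maps.

    Generates full-scale scenes under the default conditions (3-6 white
    cells, cluster probability 0.6, pairwise overlap cap 0.25), derives the
    ideal pre-segmentation map from ground truth, and counts scenes where
    the separated instance count matches exactly.  Returns
    (n_exact, n_scenes).
    """
    if seed is None:
        scene_seeds = range(n_scenes)
    else:
        scene_seeds = (np.random.SeedSequence(seed).generate_state(n_scenes)
                       % (2 ** 31))
    exact = 0
    for s in scene_seeds:
        scene = S.generate_scene(dataclasses.replace(S.SceneSpec(), seed=int(s)))
        prob = S.ground_truth_probability(scene)
        labels = W.separate_cells(prob)
        exact += int(labels.max(initial=0) == scene.n_cells)
    return exact, n_scenes
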
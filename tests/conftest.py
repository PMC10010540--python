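"""Shared fixtures: small rendered scenes and a twice-run tiny pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from tearfilm import scene
from tearfilm.optics import OpticalModel


@pytest.fixture(scope="session")
def optical_model() -> OpticalModel:
    return OpticalModel()


@pytest.fixture(scope="session")
def small_cohort() -> list[scene.Video]:
    """Nine archetype scenes (one per class) at reduced frame size, two frames each."""
    specs = scene.default_cohort(9, seed=42, frame_size=(480, 360), duration=1.0, fps=2.0)
    return [scene.render_video(s) for s in specs]


@pytest.fixture(scope="session")
def spot_video() -> scene.Video:
    """One full-size video with a single growing spot event starting mid-video."""
    spec = scene.SceneSpec(
        video_id="spotvid",
        duration=2.0,
        fps=2.0,
        frame_size=(640, 480),
        base_field=scene.BaseFieldSpec(mean=130, amplitude=8, correlation_length=90),
        events=[
            scene.BreakupEvent(
                "spot", onset=1.0, center=(264.0, 344.0), initial_size=18.0, growth_rate=2.0
            )
        ],
        seed=7,
    )
    return scene.render_video(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Run simulate -> train-eval -> detect-eval twice with identical config/seed."""
    from test_pipeline import tiny_config

    from tearfilm.pipeline import cmd_detect_eval, cmd_simulate, cmd_train_eval

    runs = {}
    for name in ("run1", "run2"):
        base = tmp_path_factory.mktemp(name)
        cfg = tiny_config()
        prov = cmd_simulate(cfg, base / "cohort")
        train_report = cmd_train_eval(cfg, base / "cohort" / "manifest.csv", base / "cv")
        detect_report = cmd_detect_eval(
            cfg,
            base / "cv" / "fold0_model.npz",
            base / "cohort" / "frames.csv",
            base / "det",
        )
        runs[name] = {
            "base": base,
            "provenance": prov,
            "train_report": train_report,
            "detect_report": detect_report,
        }
    return runs
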
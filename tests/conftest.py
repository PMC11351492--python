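"""Shared fixtures: rendered synthetic micrographs and one full
pipeline run, built once per session because rendering and fitting at
realistic scale dominate the suite's runtime."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import fibermorph as fm

# canonical two-group study conditions used by the end-to-end checks:
# one image per "year", heavy-tailed (k=0.9) vs light-tailed (k=0.5)
# bundle areas at the same scale, realistic bundle widths, mild noise.
END_TO_END_CONDITIONS = {
    "2012": {"shape_k": 0.9, "seed": 11},
    "2022": {"shape_k": 0.5, "seed": 12},
}
END_TO_END_COMMON = dict(
    scale_sigma=30.0,
    n_bundles=1200,
    image_size=(2048, 2048),
    stain_type="he",
    n_nuclei=60,
    noise_sd=4.0,
)
END_TO_END_MIN_AREA = 30.0


@pytest.fixture(scope="session")
def stain_renders():
    """One noise-free 512x512 micrograph per stain palette, with truth."""
    out = {}
    for stain in ("he", "mallory", "silver", "weigert_orcein"):
        spec = fm.SyntheticSpec(
            shape_k=0.7,
            scale_sigma=50.0,
            n_bundles=50,
            image_size=(512, 512),
            stain_type=stain,
            n_nuclei=30,
            n_artifacts=3,
            noise_sd=0.0,
            seed=11,
        )
        out[stain] = (spec, *fm.render_micrograph(spec))
    return out


def _write_two_group_images(tmp_path):
    rows = []
    for year, over in END_TO_END_CONDITIONS.items():
        spec = fm.SyntheticSpec(**END_TO_END_COMMON, **over)
        img, _truth = fm.render_micrograph(spec)
        p = tmp_path / f"im_{year}.png"
        fm.write_image(p, img.pixels)
        rows.append(
            {
                "path": str(p),
                "stain": "he",
                "year": year,
                "label": f"synthetic {year}",
                "sample_id": "1",
            }
        )
    manifest = tmp_path / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


@pytest.fixture(scope="session")
def two_group_run(tmp_path_factory):
    """Full pipeline run over the two-group synthetic study; returns
    (report, config, manifest path) so tests can also re-run it."""
    tmp = tmp_path_factory.mktemp("endtoend")
    manifest = _write_two_group_images(tmp)
    cfg = fm.RunConfig(
        manifest=manifest,
        out_dir=tmp / "out",
        min_area=END_TO_END_MIN_AREA,
        make_plots=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        report = fm.run_pipeline(cfg)
    return report, cfg, manifest
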
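"""Shared fixtures: one default synthetic bundle and one full pipeline run.

Both are session-scoped because several test modules (pipeline, acceptance)
interrogate the same artifacts; everything is derived from fixed seeds so the
suite is deterministic end to end.
"""

from __future__ import annotations

import time

import pytest

from hotregions import pipeline
from hotregions.simulate import SyntheticTruth, make_bundle

BUNDLE_SEED = 2024

# wall-clock seconds spent building the session bundle; the end-to-end
# timing criterion adds this to the pipeline run time
timings: dict[str, float] = {}


def analysis_config(bundle_dir: str, outdir: str) -> dict:
    """Run config for a synthetic bundle.

    The synthetic genome is a few megabases (non-human scale), so the caller
    uses the 1000 bp suppression span the method prescribes for non-human
    genomes; every other parameter stays at its default.
    """
    return pipeline.load_config(
        None,
        {
            "outdir": str(outdir),
            "caller": {"suppression_span": 1000},
            "paths": {
                "peak_dir": f"{bundle_dir}/peaks",
                "genome": f"{bundle_dir}/genome.fa",
                "chrom_sizes": f"{bundle_dir}/chrom.sizes",
                "cgi": f"{bundle_dir}/cgi.bed",
                "ip_reads": f"{bundle_dir}/ip.bed",
                "control_reads": f"{bundle_dir}/control.bed",
                "methylation_dir": f"{bundle_dir}/methylation",
            },
        },
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> str:
    d = tmp_path_factory.mktemp("bundle_root") / "bundle"
    t0 = time.perf_counter()
    make_bundle(d, seed=BUNDLE_SEED)
    timings["bundle_seconds"] = time.perf_counter() - t0
    return str(d)


@pytest.fixture(scope="session")
def bundle_truth(bundle_dir) -> SyntheticTruth:
    return SyntheticTruth.from_json(f"{bundle_dir}/truth.json")


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory) -> dict:
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = analysis_config(bundle_dir, str(outdir))
    t0 = time.perf_counter()
    status, manifest_path = pipeline.run(cfg)
    return {
        "cfg": cfg,
        "status": status,
        "manifest": manifest_path,
        "outdir": str(outdir),
        "seconds": time.perf_counter() - t0,
    }
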
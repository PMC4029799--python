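"""End-to-end pipeline plumbing: configs, manifests, staged runs.

``run_pipeline`` wires the stages together: load (or synthesize) images,
regularize, decompose and extract features, search per-node feature
subsets, route images through the classifier network under leave-one-out
evaluation and attach prevalence-rescaled bin confidences.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .features import extract_table
from .labels import validate_label
from .network import (
    ClassifierNode,
    PriorSpec,
    WaveletFilterNetwork,
    build_branched,
    build_sequential,
)
from .phantom import PhantomSpec, dataset_specs, generate_phantom
from .regularize import Mammogram, regularize

logger = logging.getLogger("wfc")

__all__ = ["RunConfig", "read_manifest", "phantom_feature_table", "default_network", "run_pipeline"]

#: Tuned nodes search all six moment pairs: which pair best exposes a
#: lesion type is an empirical question (the tuned feature sets are the
#: ones that best identify the anomaly), not one decided a priori.
CALC_MOMENTS = "auto"
MASS_MOMENTS = "auto"


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    n_images: int = 60
    prevalence: float = 0.33
    manifest: Optional[str] = None  # use phantoms when None
    network: str = "four-tap"  # 'four-tap' | 'six-tap' | 'sequential'
    sequential_bases: Sequence[str] = ("haar", "bior3.7", "bior2.2", "bior6.8", "db2")
    depth: Optional[int] = 5
    w: float = 0.995
    max_k: int = 3
    target_spacing: float = 200.0
    size: int = 1024
    image_size: int = 1024
    clinic_prevalence: float = 0.05
    out_dir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "sequential_bases" in data:
            data["sequential_bases"] = tuple(data["sequential_bases"])
        return cls(**data)


def read_manifest(path) -> List[Mammogram]:
    """Load images listed in a CSV manifest (filename, label, pixel_spacing_um)."""
    import imageio.v3 as iio

    path = Path(path)
    images = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"filename", "label", "pixel_spacing_um"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                label = validate_label(row["label"])
            except ValueError as e:
                raise ValueError(f"{path}:{i}: {e}") from None
            spacing = float(row["pixel_spacing_um"])
            if spacing <= 0:
                raise ValueError(f"{path}:{i}: non-positive pixel spacing")
            px = np.asarray(iio.imread(path.parent / row["filename"]), dtype=float)
            images.append(
                Mammogram(
                    pixels=px,
                    pixel_spacing=spacing,
                    label=label,
                    image_id=Path(row["filename"]).stem,
                )
            )
    return images


def default_network(kind: str = "four-tap"):
    """The stock topologies, with basis assignments mirroring the tuned
    four-tap (calcification leg Db2 -> Db8, mass leg Bior5.5 -> Haar) and
    six-tap (Bior1.5 router, Haar -> Bior2.2 calcification leg, Bior5.5 ->
    Haar mass leg) layouts."""
    if kind == "four-tap":
        return build_branched(
            [
                ClassifierNode("calc1", "db2", CALC_MOMENTS, "calcification"),
                ClassifierNode("calc2", "db8", CALC_MOMENTS, "calcification"),
            ],
            [
                ClassifierNode("mass1", "bior5.5", MASS_MOMENTS, "mass"),
                ClassifierNode("mass2", "haar", MASS_MOMENTS, "mass"),
            ],
        )
    if kind == "six-tap":
        return build_branched(
            [
                ClassifierNode("root", "bior1.5", "auto", "any"),
                ClassifierNode("calc1", "haar", CALC_MOMENTS, "calcification"),
                ClassifierNode("calc2", "bior2.2", CALC_MOMENTS, "calcification"),
            ],
            [
                ClassifierNode("mass1", "bior5.5", MASS_MOMENTS, "mass"),
                ClassifierNode("mass2", "haar", MASS_MOMENTS, "mass"),
            ],
        )
    raise ValueError(f"unknown network kind {kind!r}")


def _build_network(config: RunConfig):
    if config.network == "sequential":
        nodes = [
            ClassifierNode(f"seq{i+1}-{b}", b, "auto", "any")
            for i, b in enumerate(config.sequential_bases)
        ]
        return build_sequential(nodes, depth=config.depth)
    return default_network(config.network)


def phantom_feature_table(
    n: int,
    prevalence: float,
    seed: int,
    bases: Sequence[str],
    template: Optional[PhantomSpec] = None,
    target_spacing: float = 200.0,
    size: int = 1024,
) -> pd.DataFrame:
    """Generate -> regularize -> extract, one image at a time.

    Streaming keeps memory flat regardless of dataset size; only the
    feature rows are retained.
    """
    rows = []
    for image_id, sp in dataset_specs(n, prevalence, seed, template):
        m = generate_phantom(sp)
        m.image_id = image_id
        m = regularize(m, target_spacing=target_spacing, size=size)
        rows.append(extract_table([m], bases=bases))
    return pd.concat(rows, ignore_index=True)


def images_feature_table(
    images: Iterable[Mammogram],
    bases: Sequence[str],
    target_spacing: float = 200.0,
    size: int = 1024,
) -> pd.DataFrame:
    rows = []
    for m in images:
        reg = regularize(m, target_spacing=target_spacing, size=size)
        rows.append(extract_table([reg], bases=bases))
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    t0 = time.time()
    network = _build_network(config)
    bases = sorted({node.basis for node in network.nodes.values()})

    if config.manifest is not None:
        images = read_manifest(config.manifest)
        logger.info("loaded %d images from %s", len(images), config.manifest)
        table = images_feature_table(images, bases, config.target_spacing, config.size)
    else:
        template = PhantomSpec(image_size=config.image_size, pixel_spacing=config.target_spacing)
        table = phantom_feature_table(
            config.n_images,
            config.prevalence,
            config.seed,
            bases,
            template,
            config.target_spacing,
            config.size,
        )
    logger.info("feature table: %d images x %d columns (%.1fs)", len(table), table.shape[1], time.time() - t0)

    wfn = WaveletFilterNetwork(network, w=config.w, max_k=config.max_k).fit(table)
    n_susp = int((table["label"] != "normal").sum())
    n_norm = len(table) - n_susp
    prior = PriorSpec(p_real_s=config.clinic_prevalence, t_exp_n=n_norm, t_exp_s=n_susp)
    report = wfn.report(prior)
    report["config"] = asdict(config)
    report["n_images"] = len(table)
    report["elapsed_s"] = time.time() - t0
    logger.info(
        "network metrics: sensitivity %.3f specificity %.3f rate %.3f",
        report["sensitivity"], report["specificity"], report["classification_rate"],
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        searches = {
            nid: {
                "basis": network.nodes[nid].basis,
                "target": network.nodes[nid].tuned_target,
                "moment_pair": list(res.moment_pair or ()),
                "best_set": [f.encode() for f in res.feature_set],
                "score": res.score,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
            for nid, res in wfn.search_results_.items()
        }
        (out / "search.json").write_text(json.dumps(searches, indent=2))
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "config.json").write_text(config.to_json())
    return report
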
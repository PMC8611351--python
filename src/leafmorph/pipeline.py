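"""End-to-end analysis pipeline and fixture generation.

Runs segment -> contour -> {barcode -> vectorize -> ordinate | elastic ->
Karcher mean -> tangent PCA} -> areas -> regression over a directory of
images, a directory of contour CSVs, or a synthetic population, writing
CSV/JSON artifacts plus a manifest.  Per-leaf failures are recorded and
skipped rather than aborting the run, since damaged (fossil-like) outlines
are expected to be error-prone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcode as bc
from . import elastic as el
from . import morphometrics as mm
from .contour import (CalibratedImage, PlanarContour, extract_contour,
                      locate_base_point, remove_petiole, segment_leaf)
from .synthetic import generate_population, rasterize_contour, write_population

log = logging.getLogger("leafmorph")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def is_contour_csv(path: Path) -> bool:
    """A contour CSV is recognized by its is_basepoint header column."""
    try:
        with open(path) as fh:
            return "is_basepoint" in fh.readline()
    except OSError:
        return False


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source applies: ``source='synthetic'`` generates
    ``n_synthetic`` leaves; ``'contours'`` reads contour CSVs from
    ``input_dir``; ``'images'`` segments calibrated photographs there.
    """

    source: str = "synthetic"
    input_dir: str | None = None
    out_dir: str = "leafmorph_out"
    n_synthetic: int = 50
    param_distributions: dict | None = None
    px_per_cm: float = 152.0
    downscale: float = 8.0
    n_points: int = 200
    mode: str = "both"  # topological | geometric | both
    normalize_vectors: bool = False
    scale_invariant: bool = False
    curve_points: int = 80
    karcher_max_iter: int = 20
    max_stalk_width_cm: float = 0.3
    foreground: str = "dark"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.source not in {"synthetic", "contours", "images"}:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source != "synthetic" and not self.input_dir:
            raise ValueError(f"source={self.source!r} requires input_dir")
        if self.mode not in {"topological", "geometric", "both"}:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat key-value YAML/JSON file."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_contours(config: RunConfig) -> tuple[dict[str, PlanarContour],
                                               pd.DataFrame | None,
                                               list[dict]]:
    failures: list[dict] = []
    traits = None
    contours: dict[str, PlanarContour] = {}
    if config.source == "synthetic":
        leaves, traits = generate_population(
            config.n_synthetic, config.param_distributions,
            seed=config.seed, n_points=config.n_points)
        contours = {lid: leaf.contour
                    for lid, leaf in zip(traits["leaf_id"], leaves)}
    elif config.source == "contours":
        for path in sorted(Path(config.input_dir).glob("*.csv")):
            if not is_contour_csv(path):
                continue
            try:
                contours[path.stem] = PlanarContour.from_csv(path)
            except Exception as exc:  # noqa: BLE001 - per-leaf isolation
                failures.append({"leaf_id": path.stem, "stage": "read",
                                 "error": str(exc)})
    else:
        from PIL import Image

        paths = sorted(p for p in Path(config.input_dir).iterdir()
                       if p.suffix.lower() in IMAGE_SUFFIXES)
        for path in paths:
            try:
                px = np.asarray(Image.open(path).convert("L"), dtype=float)
                image = CalibratedImage(px, config.px_per_cm,
                                        config.downscale)
                mask = segment_leaf(image, foreground=config.foreground)
                mask = remove_petiole(mask, image,
                                      config.max_stalk_width_cm)
                contour = extract_contour(mask, image, config.n_points)
                contours[path.stem] = locate_base_point(contour)
            except Exception as exc:  # noqa: BLE001
                failures.append({"leaf_id": path.stem, "stage": "contour",
                                 "error": str(exc)})
    return contours, traits, failures


def _run_topological(contours: dict[str, PlanarContour],
                     areas: pd.DataFrame, config: RunConfig,
                     out: Path, failures: list[dict]) -> dict:
    barcodes: dict[str, bc.Barcode] = {}
    for lid, contour in contours.items():
        try:
            barcodes[lid] = bc.superlevel_barcode(
                bc.radial_distance_profile(contour))
        except Exception as exc:  # noqa: BLE001
            failures.append({"leaf_id": lid, "stage": "barcode",
                             "error": str(exc)})
    rows = [{"leaf_id": lid, "bar_rank": i, "birth_r_cm": b, "death_r_cm": d,
             "length_cm": b - d}
            for lid, code in barcodes.items()
            for i, (b, d) in enumerate(code.bars)]
    pd.DataFrame(rows).to_csv(out / "barcodes.csv", index=False)

    L = bc.pad_length(list(barcodes.values()))
    vectors = {lid: bc.vectorize_barcode(code, L)
               for lid, code in barcodes.items()}
    if config.normalize_vectors:
        vectors = {lid: bc.normalize_vector(v) for lid, v in vectors.items()}
    ids = list(vectors)
    X = np.vstack([vectors[lid].values for lid in ids])
    vec_df = pd.DataFrame(X, index=pd.Index(ids, name="leaf_id"))
    vec_df.columns = [f"bar_{i}" for i in range(X.shape[1])]
    vec_df.to_csv(out / "barcode_vectors.csv")

    model = bc.embed_population([vectors[lid] for lid in ids], method="pca")
    _write_scores(out / "topological_scores.csv", ids, model)

    regression = None
    if len(ids) >= 3:
        aligned = areas.set_index("leaf_id").loc[ids, "area_cm2"].to_numpy()
        try:
            fit = mm.area_regression(model.scores[:, :2], aligned)
            regression = {"coefficients": fit.coefficients.tolist(),
                          "r_squared": fit.r_squared, "n": fit.n}
            (out / "area_regression.json").write_text(
                json.dumps(regression, indent=2))
            fit.to_frame(aligned).assign(leaf_id=ids).to_csv(
                out / "area_predicted.csv", index=False)
        except ValueError as exc:
            log.warning("area regression skipped: %s", exc)
    return {"barcodes": barcodes, "vectors": vectors, "pad_length": L,
            "pca": model, "regression": regression}


def _run_geometric(contours: dict[str, PlanarContour], config: RunConfig,
                   out: Path, failures: list[dict]) -> dict:
    curves: dict[str, el.ShapeCurve] = {}
    for lid, contour in contours.items():
        try:
            curves[lid] = el.to_shape_curve(
                contour, n=config.curve_points,
                scale_invariant=config.scale_invariant)
        except Exception as exc:  # noqa: BLE001
            failures.append({"leaf_id": lid, "stage": "shape_curve",
                             "error": str(exc)})
    ids = list(curves)
    mean, _ = el.karcher_mean([curves[lid] for lid in ids],
                              max_iter=config.karcher_max_iter)
    pd.DataFrame(mean.points, columns=["x_cm", "y_cm"]).to_csv(
        out / "mean_shape.csv", index=False)
    model = el.tangent_pca([curves[lid] for lid in ids], mean)
    _write_scores(out / "geometric_scores.csv", ids, model)
    return {"curves": curves, "mean": mean, "pca": model}


def _write_scores(path: Path, ids: list[str], model) -> None:
    k = min(model.scores.shape[1], 10)
    df = pd.DataFrame(model.scores[:, :k],
                      index=pd.Index(ids, name="leaf_id"),
                      columns=[f"PC{i + 1}" for i in range(k)])
    df.loc["__explained_variance_ratio__"] = \
        model.explained_variance_ratio[:k]
    df.to_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle.

    Identical config + seed reproduces every numeric artifact exactly.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contours, traits, failures = _load_contours(config)
    if traits is not None:
        traits.to_csv(out / "traits.csv", index=False)
    for lid, contour in contours.items():
        contour.to_csv(out / f"contour_{lid}.csv")

    areas = mm.area_table(contours)
    areas.to_csv(out / "areas.csv", index=False)

    bundle: dict = {"contours": contours, "areas": areas, "traits": traits}
    if config.mode in {"topological", "both"} and contours:
        bundle["topological"] = _run_topological(contours, areas, config,
                                                 out, failures)
    if config.mode in {"geometric", "both"} and contours:
        bundle["geometric"] = _run_geometric(contours, config, out, failures)

    manifest = {"config": asdict(config),
                "seed": config.seed,
                "n_leaves": len(contours),
                "n_failures": len(failures),
                "failures": failures,
                "versions": {"python": platform.python_version(),
                             "numpy": np.__version__,
                             "pandas": pd.__version__}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def make_fixtures(out_dir: str | Path, n: int = 12, seed: int = 0,
                  param_distributions: dict | None = None,
                  rasterize: bool = False, px_per_cm: float = 50.0,
                  overwrite: bool = False) -> Path:
    """Write a self-contained fixture directory.

    Contains per-leaf contour CSVs, the trait table, the ten-vertex
    worked-example radial profile, and (optionally) rendered PNG masks for
    exercising the image path.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    leaves, traits = generate_population(n, param_distributions, seed=seed)
    write_population(leaves, traits, out)
    pd.DataFrame({"d_cm": bc.EXAMPLE_RADIAL_PROFILE}).to_csv(
        out / "example_profile.csv", index=False)
    if rasterize:
        from PIL import Image

        for lid, leaf in zip(traits["leaf_id"], leaves):
            img = rasterize_contour(leaf.contour, px_per_cm=px_per_cm)
            Image.fromarray(img.pixels).save(out / f"{lid}.png")
    return out
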
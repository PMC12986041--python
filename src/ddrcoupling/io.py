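"""TSV/JSON readers and writers for expression matrices, sample
annotations and generator specs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import SyntheticSpec


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    """Genes x samples TSV; first column ``gene_id``."""
    out = expression.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id rows: {dupes}")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "batch"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return ann


def spec_to_json(spec: SyntheticSpec, path: str | Path) -> None:
    """Serialise a SyntheticSpec; tuple keys flattened as 'a||b'."""

    def flat(d: dict) -> dict:
        return {"||".join(map(str, k)) if isinstance(k, tuple) else k: v for k, v in d.items()}

    payload = {
        "genes": list(spec.genes),
        "hub": spec.hub,
        "stage_sizes": spec.stage_sizes,
        "stage_means": flat(spec.stage_means),
        "hub_variance": spec.hub_variance,
        "planted_R2": flat(spec.planted_R2),
        "noise_variance": flat(spec.noise_variance),
        "batch_count": spec.batch_count,
        "batch_additive": flat(spec.batch_additive),
        "batch_multiplicative": flat(spec.batch_multiplicative),
        "bimodal_genes": {g: list(v) for g, v in spec.bimodal_genes.items()},
        "seed": spec.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def spec_from_json(path: str | Path) -> SyntheticSpec:
    raw = json.loads(Path(path).read_text())

    def unflat(d: dict, batch: bool = False) -> dict:
        out = {}
        for k, v in d.items():
            a, b = k.split("||")
            out[(a, int(b) if batch else b)] = v
        return out

    spec = SyntheticSpec(
        genes=tuple(raw["genes"]),
        hub=raw["hub"],
        stage_sizes={k: int(v) for k, v in raw["stage_sizes"].items()},
        stage_means=unflat(raw["stage_means"]),
        hub_variance=raw["hub_variance"],
        planted_R2=unflat(raw["planted_R2"]),
        noise_variance=unflat(raw["noise_variance"]),
        batch_count=int(raw["batch_count"]),
        batch_additive=unflat(raw["batch_additive"], batch=True),
        batch_multiplicative=unflat(raw["batch_multiplicative"], batch=True),
        bimodal_genes={g: tuple(v) for g, v in raw["bimodal_genes"].items()},
        seed=int(raw["seed"]),
    )
    spec.validate()
    return spec
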
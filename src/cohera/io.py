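"""File formats, configuration and the pipeline driver.

Transcripts and events travel as TSV (tokens can contain commas);
images as NIfTI-1 via nibabel; configuration as YAML. Time is in
seconds, 0-based from run start for events; block indices are 1-based
within a trial. The defaults in :class:`PipelineConfig` are the
analysis constants used throughout the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import design as dsg
from .coherence import Response
from .semantic_space import build_space

__all__ = [
    "PipelineConfig",
    "read_transcripts",
    "write_transcripts",
    "read_events",
    "write_events",
    "read_covariates",
    "save_nifti",
    "load_nifti",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRANSCRIPT_COLUMNS = ["participant_id", "prompt_id", "word_index", "token",
                      "onset_s", "run_id"]


@dataclass
class PipelineConfig:
    """Analysis constants; defaults are the study's stated values."""

    window_length: int = 20  # words per coherence window
    block_length: float = 5.0  # s
    period_length: float = 50.0  # s speech production period
    planning_duration: float = 8.0  # s
    baseline_duration: float = 15.0  # s automatic speech
    winsor_sd: float = 2.0
    highpass: float = 180.0  # s
    tr: float = 2.2  # s
    voxel_p: float = 0.005
    n_sim: int = 5000
    roi_threshold: float = 0.30
    medial_cut_mm: float = 30.0
    lsa_k: int = 300
    min_doc_freq: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        defaults = cls()
        unknown = set(raw) - set(asdict(defaults))
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if val != getattr(defaults, key):
                logger.info("config override: %s = %r", key, val)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_transcripts(path: str | Path) -> list[Response]:
    """Read a transcript TSV into responses.

    Columns: participant_id, prompt_id, word_index (contiguous from 1
    within participant x prompt), token, onset_s (optional), run_id.
    Schema violations name the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"token": str})
    if df.empty:
        warnings.warn(f"{path}: empty transcript file", stacklevel=2)
        return []
    missing = [c for c in ("participant_id", "prompt_id", "word_index", "token")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    responses = []
    for (pid, prompt), grp in df.groupby(["participant_id", "prompt_id"],
                                         sort=True):
        grp = grp.sort_values("word_index")
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(grp["word_index"].to_numpy(), expected):
            bad = grp.index[grp["word_index"].to_numpy() != expected].tolist()
            raise ValueError(
                f"{path}: non-contiguous word_index for ({pid}, {prompt}) "
                f"at rows {bad}"
            )
        onsets = None
        if "onset_s" in grp.columns and grp["onset_s"].notna().all():
            onsets = grp["onset_s"].to_numpy(dtype=float)
        period = float(onsets[-1]) if onsets is not None else 50.0
        responses.append(Response(
            participant_id=str(pid),
            prompt_id=str(prompt),
            tokens=grp["token"].tolist(),
            word_onsets=onsets,
            period_length=max(period, 50.0),
        ))
    return responses


def write_transcripts(responses: list[Response], path: str | Path,
                      run_id: int = 0) -> None:
    rows = []
    for r in responses:
        onsets = r.word_onsets
        for i, tok in enumerate(r.tokens):
            rows.append({
                "participant_id": r.participant_id,
                "prompt_id": r.prompt_id,
                "word_index": i + 1,
                "token": tok,
                "onset_s": float(onsets[i]) if onsets is not None else np.nan,
                "run_id": run_id,
            })
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_events(path: str | Path) -> list[dsg.TrialTiming]:
    """BIDS-style events TSV: onset, duration, trial_type, run."""
    df = pd.read_csv(path, sep="\t")
    needed = {"onset", "duration", "trial_type"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: events file needs columns {sorted(needed)}")
    if (df["onset"] < 0).any() or (df["duration"] <= 0).any():
        raise ValueError(f"{path}: onsets must be >= 0 and durations > 0")
    run = df["run"] if "run" in df.columns else pd.Series(0, index=df.index)
    return [
        dsg.TrialTiming(
            condition=row["trial_type"],
            onset=float(row["onset"]),
            duration=float(row["duration"]),
            run_id=int(run.loc[i]),
        )
        for i, row in df.iterrows()
    ]


def write_events(timings: list[dsg.TrialTiming], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"onset": t.onset, "duration": t.duration,
             "trial_type": t.condition, "run": t.run_id}
            for t in timings
        ]
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Whitespace- or tab-delimited per-volume covariate table
    (motion parameters, noise components)."""
    return pd.read_csv(path, sep=r"\s+", header=None).rename(
        columns=lambda j: f"c{j}"
    )


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def run_pipeline(
    config: PipelineConfig,
    transcript_path: str | Path,
    corpus_path: str | Path,
    out_dir: str | Path,
    events_path: str | Path | None = None,
) -> dict:
    """Score coherence for every response and write stage outputs.

    Builds the semantic space from the corpus file (one document per
    line), computes leave-one-out global and local coherence for every
    response, aggregates 5-s block values, and writes coherence tables
    plus a JSON provenance summary (config hash, seed). Deterministic
    stages are bit-identical across reruns with the same inputs.
    """
    from .semantic_space import Corpus

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = Corpus.from_lines(corpus_path)
    k = min(config.lsa_k, len(corpus.documents) - 1)
    space = build_space(corpus, k=k, min_doc_freq=config.min_doc_freq)
    responses = read_transcripts(transcript_path)
    if not responses:
        raise ValueError("pipeline halted at stage 'transcripts': no responses")

    by_prompt: dict[str, list[Response]] = {}
    for r in responses:
        by_prompt.setdefault(r.prompt_id, []).append(r)

    block_rows = []
    for prompt_id, group in sorted(by_prompt.items()):
        for r in group:
            proto = coh.prototype_vector(group, exclude=r.participant_id,
                                         space=space)
            series = coh.global_coherence_series(
                r, proto, space, window=config.window_length
            )
            blocks = coh.block_coherence(series, r,
                                         block_length=config.block_length)
            for b in blocks:
                block_rows.append({
                    "participant_id": r.participant_id,
                    "prompt_id": prompt_id,
                    "block_index": b.block_index,
                    "global_coherence": b.value,
                    "n_words": b.n_words_in_block,
                    "substituted": b.substituted,
                })
    block_table = pd.DataFrame(block_rows)
    block_table.to_csv(out / "block_coherence.tsv", sep="\t", index=False)

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_responses": len(responses),
        "n_prompts": len(by_prompt),
        "mean_block_coherence": float(block_table["global_coherence"].mean()),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    config.to_yaml(out / "config_used.yaml")
    return summary
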
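"""Derived statistics: translation dependence of HSR induction,
flow-cytometry summarization, ensemble variability, and image ratios.

The central statistic is the translation dependence of heat shock gene
induction, computed from RNA-seq counts of Hsf1 target genes measured
with and without the translation inhibitor cycloheximide (CHX):

    dependence_g = 1 - fold_CHX(g) / fold_untreated(g)

where each fold change is heat shock over non-heat-shock expression
within its CHX stratum. A dependence of 0.7 means 70% of a gene's
induction requires ongoing translation.
"""

from __future__ import annotations

import io
import urllib.request
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DomainError
from .simulate import Ensemble

HEAT_LEVELS = ("NHS", "HS")
CHX_LEVELS = ("untreated", "CHX")

_META_COLUMNS = ("sample", "heat", "chx", "replicate")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTable:
    """Gene-by-sample read counts with (heat, CHX, replicate) labels.

    ``counts`` is a genes × samples DataFrame of non-negative integers;
    ``samples`` is a samples-indexed DataFrame with columns
    ``heat`` (NHS|HS), ``chx`` (untreated|CHX) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise DomainError("counts columns must match sample metadata index")
        for col in ("heat", "chx", "replicate"):
            if col not in self.samples.columns:
                raise DomainError(f"sample metadata missing column {col!r}")
        bad_heat = set(self.samples["heat"]) - set(HEAT_LEVELS)
        bad_chx = set(self.samples["chx"]) - set(CHX_LEVELS)
        if bad_heat:
            raise DomainError(f"invalid heat labels: {sorted(bad_heat)}")
        if bad_chx:
            raise DomainError(f"invalid chx labels: {sorted(bad_chx)}")
        if (self.counts.to_numpy() < 0).any():
            raise DomainError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, heat: str, chx: str) -> list:
        mask = (self.samples["heat"] == heat) & (self.samples["chx"] == chx)
        return list(self.samples.index[mask])

    def to_csv(self, path) -> None:
        """Single CSV with a commented sample-metadata header block."""
        with open(path, "w", newline="") as fh:
            fh.write("# sample_metadata: " + ",".join(_META_COLUMNS) + "\n")
            for name, row in self.samples.iterrows():
                fh.write(f"# {name},{row['heat']},{row['chx']},{row['replicate']}\n")
            self.counts.to_csv(fh, index_label="gene")

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        meta_rows = []
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# sample_metadata:"):
                    continue
                if line.startswith("#"):
                    meta_rows.append(line[1:].strip().split(","))
                else:
                    body.append(line)
        if not meta_rows:
            raise DomainError(f"{path}: no sample-metadata header block found")
        samples = pd.DataFrame(meta_rows, columns=list(_META_COLUMNS)).set_index("sample")
        counts = pd.read_csv(io.StringIO("".join(body)), index_col="gene")
        return cls(counts=counts, samples=samples)


@dataclass(frozen=True)
class FlowSample:
    """Per-cell fluorescence and side-scatter for one strain × time point."""

    fluorescence: np.ndarray
    scatter: np.ndarray
    label: str = ""
    time_min: float = float("nan")

    def __post_init__(self) -> None:
        fl = np.asarray(self.fluorescence, dtype=float)
        sc = np.asarray(self.scatter, dtype=float)
        object.__setattr__(self, "fluorescence", fl)
        object.__setattr__(self, "scatter", sc)
        if fl.size == 0 or sc.size != fl.size:
            raise DomainError("fluorescence and scatter must be equal-length, non-empty")
        if np.any(sc <= 0):
            raise DomainError("side scatter must be strictly positive")
        if np.any(fl <= 0):
            raise DomainError("fluorescence must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.size


# ---------------------------------------------------------------------------
# RNA-seq fold changes and translation dependence
# ---------------------------------------------------------------------------

def relative_expression(
    table: CountTable,
    pseudocount: float = 0.5,
    depth_normalize: bool = True,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Per-gene HS/NHS fold change within each CHX stratum.

    Counts are first scaled by total library size per sample (unless
    ``depth_normalize=False``), averaged over replicates, and ratioed
    with a pseudocount guarding zero denominators:

        fold = (mean_HS + pseudocount) / (mean_NHS + pseudocount)

    Returns a DataFrame indexed by gene with one column per CHX stratum
    (``untreated``, ``CHX``). With ``per_replicate=True`` replicates are
    paired by their replicate id instead of averaged, and columns are
    (stratum, replicate) tuples.
    """
    if pseudocount < 0:
        raise DomainError(f"pseudocount must be >= 0, got {pseudocount}")
    counts = table.counts.astype(float)
    if depth_normalize:
        depth = counts.sum(axis=0)
        if (depth <= 0).any():
            raise DomainError("cannot depth-normalize a sample with zero total counts")
        counts = counts / depth * depth.mean()

    def stratum_mean(heat: str, chx: str) -> pd.Series | pd.DataFrame:
        cols = table.samples_for(heat, chx)
        if not cols:
            raise DomainError(f"missing stratum: heat={heat!r}, chx={chx!r}")
        if per_replicate:
            reps = table.samples.loc[cols, "replicate"]
            sub = counts[cols].copy()
            sub.columns = list(reps)
            return sub
        return counts[cols].mean(axis=1)

    out = {}
    for chx in CHX_LEVELS:
        hs = stratum_mean("HS", chx)
        nhs = stratum_mean("NHS", chx)
        fold = (hs + pseudocount) / (nhs + pseudocount)
        if per_replicate:
            for rep in fold.columns:
                out[(chx, rep)] = fold[rep]
        else:
            out[chx] = fold
    return pd.DataFrame(out)


def translation_dependence(
    fold_untreated: pd.Series,
    fold_chx: pd.Series,
) -> tuple[pd.Series, dict]:
    """Fraction of heat shock induction that requires ongoing translation.

    ``1 - fold_CHX / fold_untreated`` per gene; at most 1, and negative
    when CHX treatment increased apparent induction. Returns the
    per-gene series and a summary dict with the cross-gene arithmetic
    ``mean`` (the headline statistic) and ``median``.
    """
    fu = pd.Series(fold_untreated, dtype=float)
    fc = pd.Series(fold_chx, dtype=float)
    if set(fu.index) != set(fc.index):
        raise DomainError("gene sets of the two fold-change vectors differ")
    fc = fc.reindex(fu.index)
    if (fu <= 0).any() or (fc <= 0).any():
        raise DomainError("fold changes must be strictly positive")
    dep = 1.0 - fc / fu
    dep.name = "translation_dependence"
    return dep, {"mean": float(dep.mean()), "median": float(dep.median()), "n_genes": int(dep.size)}


def translation_dependence_from_table(
    table: CountTable, pseudocount: float = 0.5, depth_normalize: bool = True
) -> tuple[pd.Series, dict]:
    """Convenience: fold changes then dependence straight from a CountTable."""
    folds = relative_expression(table, pseudocount=pseudocount, depth_normalize=depth_normalize)
    return translation_dependence(folds["untreated"], folds["CHX"])


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

def median_reporter(sample: FlowSample) -> float:
    """Median over cells of side-scatter-normalized fluorescence.

    Scatter normalization removes cell-size dependence; the median is
    robust to the right-skewed tail of per-cell fluorescence.
    """
    return float(np.median(sample.fluorescence / sample.scatter))


# ---------------------------------------------------------------------------
# Ensemble variability
# ---------------------------------------------------------------------------

def ensemble_variation(ensemble: Ensemble, time: float) -> dict:
    """Spread of reporter output across ensemble replicates at one time.

    Returns ``cv`` (population coefficient of variation of YFP across
    trajectories) and ``range_over_mean`` ((max − min)/mean) — both
    dimensionless and invariant to rescaling all trajectories together.
    """
    if len(ensemble) < 2:
        raise DomainError("ensemble variation needs at least 2 trajectories")
    values = []
    for traj in ensemble.trajectories:
        if not (traj.times[0] <= time <= traj.times[-1]):
            raise DomainError(
                f"time {time} outside trajectory span [{traj.times[0]}, {traj.times[-1]}]"
            )
        values.append(float(np.interp(time, traj.times, traj.yfp)))
    values = np.array(values)
    mean = values.mean()
    if mean == 0:
        raise DomainError("mean YFP is zero; relative spread undefined")
    return {
        "cv": float(values.std(ddof=0) / mean),
        "range_over_mean": float((values.max() - values.min()) / mean),
        "n": int(values.size),
    }


# ---------------------------------------------------------------------------
# Imaging: nucleolar ring enrichment
# ---------------------------------------------------------------------------

def ring_to_cell_ratio(
    intensity: np.ndarray, ring_mask: np.ndarray, cell_mask: np.ndarray
) -> float:
    """Mean intensity in the peri-nucleolar ring over mean intensity in
    the whole cell.

    Quantifies enrichment of a labeled protein at the nucleolar
    periphery: 1 means no enrichment. Invariant to global intensity
    scaling but not to background offsets. The ring must be contained in
    the cell mask.
    """
    intensity = np.asarray(intensity, dtype=float)
    ring_mask = np.asarray(ring_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if intensity.shape != ring_mask.shape or intensity.shape != cell_mask.shape:
        raise DomainError("intensity and masks must share one shape")
    if not ring_mask.any():
        raise DomainError("ring mask is empty")
    if not cell_mask.any():
        raise DomainError("cell mask is empty")
    if np.any(ring_mask & ~cell_mask):
        raise DomainError("ring mask must be contained in the cell mask")
    cell_mean = intensity[cell_mask].mean()
    if cell_mean == 0:
        raise DomainError("mean cell intensity is zero; ratio undefined")
    return float(intensity[ring_mask].mean() / cell_mean)


# ---------------------------------------------------------------------------
# Optional GEO fetch (network, strictly opt-in)
# ---------------------------------------------------------------------------

GEO_ACCESSION = "GSE152916"


def fetch_geo_supplementary(
    accession: str = GEO_ACCESSION,
    dest_dir: str = ".",
    allow_network: bool = False,
    timeout: float = 60.0,
) -> list[str]:
    """Download the supplementary files of a GEO series (opt-in).

    Network access is refused unless ``allow_network=True`` — all desk
    analyses run on synthetic or local tables. Returns local paths of
    the downloaded files.
    """
    if not allow_network:
        raise DomainError(
            "network access is disabled; pass allow_network=True (or --allow-network) "
            "to fetch GEO data, or supply a local counts CSV"
        )
    import os
    import re

    stub = accession[:-3] + "nnn"
    base = f"https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}/{accession}/suppl/"
    with urllib.request.urlopen(base, timeout=timeout) as resp:
        listing = resp.read().decode("utf-8", errors="replace")
    names = sorted(set(re.findall(r'href="([^"?/][^"]*)"', listing)))
    paths = []
    os.makedirs(dest_dir, exist_ok=True)
    for name in names:
        out = os.path.join(dest_dir, name)
        with urllib.request.urlopen(base + name, timeout=timeout) as resp, open(out, "wb") as fh:
            fh.write(resp.read())
        paths.append(out)
    return paths
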
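"""Probe tables, methylation matrices, class recoding and the beta/M transform.

A :class:`ProbeSet` couples an annotated probe map (ID, chromosome, position,
functional-class memberships) with a beta matrix — per-probe methylation
fractions in [0, 1] for each of n >= 2 named samples.  Statistics downstream
are computed on M-values, the logit2 transform of beta, which is
variance-stabilised compared to the bounded beta scale.
"""

from __future__ import annotations

import os
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eleven functional classes assigned by the 450K manifest: six describe
#: the probe's relation to a gene, five its relation to a CpG island.
GENE_CLASSES = ("Body", "1stExon", "3'UTR", "5'UTR", "TSS200", "TSS1500")
ISLAND_CLASSES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf")
ALL_CLASSES = GENE_CLASSES + ISLAND_CLASSES

#: Grouping used by recode scheme 1: relation to gene body / transcription
#: start site / CpG island.
GENE_TSS_ISLAND_MAP: dict[str, str] = {
    "Body": "gene",
    "1stExon": "gene",
    "3'UTR": "gene",
    "5'UTR": "gene",
    "TSS200": "tss",
    "TSS1500": "tss",
    "Island": "island",
    "N_Shore": "island",
    "S_Shore": "island",
    "N_Shelf": "island",
    "S_Shelf": "island",
}

SINGLE_CLASS_LABEL = "all"

_CHROM_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, MT, then others alphabetically."""
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    if c.isdigit():
        return (int(c), "")
    if c.upper() in _CHROM_SPECIAL:
        return (_CHROM_SPECIAL[c.upper()], "")
    return (26, c)


@dataclass(frozen=True)
class MTransformConfig:
    """Clipping used before the logit so M is finite for beta in {0, 1}."""

    epsilon: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")


def m_from_beta(beta, cfg: MTransformConfig | None = None):
    """logit2 transform: M = log2(beta' / (1 - beta')) with beta' clipped to
    [epsilon, 1 - epsilon].  Missing (NaN) values pass through unchanged.

    Accepts scalars or arrays.
    """
    cfg = cfg or MTransformConfig()
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        clipped = np.clip(b, cfg.epsilon, 1.0 - cfg.epsilon)
        m = np.log2(clipped / (1.0 - clipped))
    m = np.where(np.isnan(b), np.nan, m)
    if np.isscalar(beta) or b.ndim == 0:
        return float(m)
    return m


def beta_from_m(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M).  NaN passes through."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    if out.ndim == 0:
        return float(out)
    return out


class ClassMap:
    """Mapping from raw manifest labels to analysis classes.

    The three built-in schemes follow the tool's recode parameter:
    ``keep_all_11`` (0) is the identity on the eleven manifest classes,
    ``group_gene_tss_island`` (1) groups them by relation to gene / TSS /
    CpG island, and ``single_class`` (2) puts every probe — annotated or
    not — into one class.
    """

    SCHEMES = ("keep_all_11", "group_gene_tss_island", "single_class")

    def __init__(self, scheme: str = "group_gene_tss_island",
                 mapping: Mapping[str, str] | None = None):
        if mapping is not None:
            self.scheme = "custom"
            self.mapping = dict(mapping)
        else:
            if scheme not in self.SCHEMES:
                raise ValueError(
                    f"unknown scheme {scheme!r}; expected one of {self.SCHEMES} "
                    "or a custom mapping")
            self.scheme = scheme
            if scheme == "keep_all_11":
                self.mapping = {c: c for c in ALL_CLASSES}
            elif scheme == "group_gene_tss_island":
                self.mapping = dict(GENE_TSS_ISLAND_MAP)
            else:  # single_class
                self.mapping = {}

    @classmethod
    def from_recode(cls, recode: int) -> "ClassMap":
        """Numeric recode parameter: 0, 1 or 2."""
        try:
            return cls(scheme=cls.SCHEMES[recode])
        except (IndexError, TypeError):
            raise ValueError(f"recode must be 0, 1 or 2, got {recode!r}")

    def apply(self, raw_classes: Iterable[str]) -> frozenset[str]:
        """Map a probe's raw labels to its set of analysis classes."""
        if self.scheme == "single_class":
            return frozenset({SINGLE_CLASS_LABEL})
        out = {self.mapping[r] for r in raw_classes if r in self.mapping}
        return frozenset(out)

    def validate(self, observed_raw_labels: Iterable[str]) -> None:
        """Warn about custom-map entries that match no observed raw label."""
        observed = set(observed_raw_labels)
        unknown = set(self.mapping) - observed
        if self.scheme == "custom" and unknown:
            logger.warning(
                "custom class map references %d label(s) absent from the "
                "annotation: %s", len(unknown), sorted(unknown))


@dataclass
class ColumnSpec:
    """Column names of the annotation table; defaults match a 450K manifest."""

    probe_id: str = "IlmnID"
    chrom: str = "CHR"
    position: str = "MAPINFO"
    class_columns: tuple[str, ...] = (
        "UCSC_RefGene_Group", "Relation_to_UCSC_CpG_Island")
    beta_probe_id: str | None = None  # default: first column of beta table


class ProbeSet:
    """Sorted probe map plus aligned beta matrix.

    Attributes
    ----------
    probes : pandas.DataFrame
        One row per probe with columns ``probe_id``, ``chrom``, ``position``,
        ``raw_classes`` (frozenset) and, after :meth:`recode`,
        ``analysis_classes`` (frozenset).  Rows are sorted by
        (chromosome in natural order, position, probe_id); this order is
        canonical and shared with ``beta``.
    sample_names : list of str
    beta : numpy.ndarray, shape (n_probes, n_samples)
        Methylation fractions; NaN marks missing values.
    """

    def __init__(self, probes: pd.DataFrame, beta: np.ndarray,
                 sample_names: Sequence[str]):
        if len(sample_names) < 2:
            raise ValueError("a ProbeSet requires at least 2 samples")
        if beta.shape != (len(probes), len(sample_names)):
            raise ValueError("beta matrix shape does not match probes/samples")
        ids = probes["probe_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate probe IDs: {dupes[:5]}")
        bad = ~(np.isnan(beta) | ((beta >= 0.0) & (beta <= 1.0)))
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"beta value outside [0, 1] for probe "
                f"{probes['probe_id'].iloc[i]!r}")
        if (probes["position"] < 1).any():
            bad_id = probes.loc[probes["position"] < 1, "probe_id"].iloc[0]
            raise ValueError(f"position < 1 for probe {bad_id!r}")
        order = _canonical_order(probes)
        self.probes = probes.iloc[order].reset_index(drop=True)
        self.beta = np.asarray(beta, dtype=float)[order]
        self.sample_names = list(sample_names)
        self.class_map: ClassMap | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def __len__(self) -> int:
        return len(self.probes)

    def m_values(self, cfg: MTransformConfig | None = None) -> np.ndarray:
        """M-value matrix aligned with ``probes`` / ``beta``."""
        return m_from_beta(self.beta, cfg)

    def recode(self, cm: ClassMap) -> "ProbeSet":
        """Populate ``analysis_classes`` in place (returns self).

        Under ``keep_all_11`` and ``group_gene_tss_island`` a probe with no
        mapped raw label receives an empty set and is thereby excluded from
        region finding; under ``single_class`` every probe gets one label.
        """
        observed: set[str] = set()
        for rc in self.probes["raw_classes"]:
            observed |= rc
        cm.validate(observed)
        self.probes = self.probes.copy()
        self.probes["analysis_classes"] = [
            cm.apply(rc) for rc in self.probes["raw_classes"]]
        self.class_map = cm
        return self

    def annotated_mask(self) -> np.ndarray:
        """Boolean mask of probes carrying at least one analysis class."""
        if "analysis_classes" not in self.probes:
            raise ValueError("ProbeSet has not been recoded")
        return np.array(
            [len(ac) > 0 for ac in self.probes["analysis_classes"]], dtype=bool)

    def average_replicates(self, groups: Mapping[str, Sequence[str]]) -> "ProbeSet":
        """Collapse technical replicates by the per-probe mean beta.

        ``groups`` maps each output sample name to the input replicate
        columns it averages (NaN-aware mean).  Averaging is always an
        explicit pre-step, never implicit.
        """
        cols = []
        for name, members in groups.items():
            idx = [self.sample_names.index(m) for m in members]
            with np.errstate(invalid="ignore"):
                cols.append(np.nanmean(self.beta[:, idx], axis=1))
        beta = np.column_stack(cols)
        ps = ProbeSet(self.probes.drop(columns=["analysis_classes"],
                                       errors="ignore"),
                      beta, list(groups))
        if self.class_map is not None:
            ps.recode(self.class_map)
        return ps


def _canonical_order(probes: pd.DataFrame) -> np.ndarray:
    keys = pd.DataFrame({
        "ck": [chrom_sort_key(c) for c in probes["chrom"]],
        "pos": probes["position"].to_numpy(),
        "pid": probes["probe_id"].to_numpy(),
    })
    return keys.sort_values(["ck", "pos", "pid"], kind="mergesort").index.to_numpy()


def _split_raw_classes(value) -> frozenset[str]:
    """Split a semicolon-separated annotation field into a deduplicated set."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    parts = [p.strip() for p in re.split(r";", str(value))]
    return frozenset(p for p in parts if p)


def _read_table(source, **kwargs) -> pd.DataFrame:
    """Read delimited text with auto-detected separator (TSV or CSV)."""
    if isinstance(source, (str, bytes, os.PathLike)) or hasattr(source, "read"):
        return pd.read_csv(source, sep=None, engine="python", **kwargs)
    raise TypeError(f"cannot read table from {type(source)}")


def parse_probe_table(annotation_source, beta_source,
                      column_spec: ColumnSpec | None = None) -> ProbeSet:
    """Parse annotation + beta delimited-text tables into a ProbeSet.

    The two tables are joined on the probe ID; probes present in only one of
    them are dropped with a logged count.  Duplicate probe IDs, fewer than two
    sample columns, or beta values outside [0, 1] are hard errors.
    """
    spec = column_spec or ColumnSpec()
    ann = _read_table(annotation_source)
    bet = _read_table(beta_source)

    for col in (spec.probe_id, spec.chrom, spec.position):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    beta_id = spec.beta_probe_id or bet.columns[0]
    sample_names = [c for c in bet.columns if c != beta_id]
    if len(sample_names) < 2:
        raise ValueError("beta table must have >= 2 sample columns")

    ann_ids = ann[spec.probe_id].astype(str)
    bet_ids = bet[beta_id].astype(str)
    if ann_ids.duplicated().any():
        raise ValueError("duplicate probe IDs in annotation table")
    if bet_ids.duplicated().any():
        raise ValueError("duplicate probe IDs in beta table")

    common = set(ann_ids) & set(bet_ids)
    n_dropped = (len(ann) - len(common)) + (len(bet) - len(common))
    if n_dropped:
        logger.warning("%d probe(s) dropped: present in only one input table",
                       n_dropped)
    keep = ann_ids.isin(common).to_numpy()
    ann = ann.loc[keep].reset_index(drop=True)
    ann_ids = ann_ids[keep].reset_index(drop=True)

    bet = bet.assign(**{beta_id: bet_ids}).set_index(beta_id)
    bet = bet.loc[ann_ids.to_numpy(), sample_names]
    for col in sample_names:
        vals = pd.to_numeric(bet[col], errors="coerce")
        bad = vals.isna() & bet[col].notna() & (bet[col].astype(str).str.strip() != "") \
            & ~bet[col].astype(str).str.upper().isin(["NA", "NAN"])
        if bad.any():
            raise ValueError(
                f"non-numeric beta value for probe {bad.idxmax()!r} "
                f"in sample {col!r}")
        bet[col] = vals

    raw = [frozenset()] * len(ann)
    for cc in spec.class_columns:
        if cc not in ann.columns:
            continue
        raw = [rc | _split_raw_classes(v) for rc, v in zip(raw, ann[cc])]

    probes = pd.DataFrame({
        "probe_id": ann_ids.to_numpy(),
        "chrom": ann[spec.chrom].astype(str).to_numpy(),
        "position": pd.to_numeric(ann[spec.position]).astype(int).to_numpy(),
        "raw_classes": raw,
    })
    return ProbeSet(probes, bet.to_numpy(dtype=float), sample_names)
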
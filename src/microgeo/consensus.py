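"""Per-sample consensus marker-gene sequences from recruited-read pileups.

A sample's recruited reads over the marker are reduced to per-position base
counts; the consensus base at a position is the strict-majority base, with
'N' at ties or where depth falls below a minimum. Samples then pass three
quality gates (total recruited reads, mean single-copy core-gene coverage,
fraction of core-gene reads binned to the focal ecotype) before their
consensus sequences are binarized into a samples x variant-allele matrix.

Indels are out of model: observations are substitutions at marker positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ValidationError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

QC_GATES = ("min_reads", "min_sccg_cov", "min_frac_hlii")


@dataclass
class PileupSet:
    """Stacks of read-base observations over marker positions, per sample.

    ``counts`` maps sample_id -> (marker_length x 4) integer array of base
    counts in A,C,G,T order. ``n_reads`` is the number of recruited reads
    per sample (not the per-position depth when reads are shorter than the
    marker).
    """

    marker_length: int
    reference_seq: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.reference_seq) != self.marker_length:
            raise ValidationError(
                f"reference length {len(self.reference_seq)} != marker_length "
                f"{self.marker_length}"
            )
        bad = set(self.reference_seq.upper()) - set(BASES)
        if bad:
            raise ValidationError(f"reference contains invalid bases {sorted(bad)}")
        for sid, c in self.counts.items():
            c = np.asarray(c)
            if c.shape != (self.marker_length, 4):
                raise ValidationError(
                    f"sample {sid!r}: counts shape {c.shape} != "
                    f"({self.marker_length}, 4)"
                )
            if np.any(c < 0):
                raise ValidationError(f"sample {sid!r}: negative base count")
            self.counts[sid] = c.astype(np.int64)
            self.n_reads.setdefault(sid, int(c.sum()))

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    def add_observations(self, sample_id: str, positions, bases, n=None) -> None:
        """Accumulate (position, base[, count]) observations for one sample."""
        positions = np.asarray(positions, dtype=int)
        if np.any((positions < 0) | (positions >= self.marker_length)):
            raise ValidationError(
                f"sample {sample_id!r}: position outside [0, {self.marker_length})"
            )
        base_idx = np.array([BASE_INDEX[b] for b in bases], dtype=int)
        c = self.counts.setdefault(
            sample_id, np.zeros((self.marker_length, 4), dtype=np.int64))
        counts = np.ones(len(positions), dtype=np.int64) if n is None \
            else np.asarray(n, dtype=np.int64)
        np.add.at(c, (positions, base_idx), counts)
        self.n_reads[sample_id] = self.n_reads.get(sample_id, 0)

    def to_frame(self) -> pd.DataFrame:
        """Long TSV view: sample_id, position, base, count (count > 0 rows)."""
        recs = []
        for sid in self.samples:
            c = self.counts[sid]
            pos, bi = np.nonzero(c)
            recs.append(pd.DataFrame({
                "sample_id": sid,
                "position": pos,
                "base": [BASES[i] for i in bi],
                "count": c[pos, bi],
            }))
        if not recs:
            return pd.DataFrame(columns=["sample_id", "position", "base", "count"])
        return pd.concat(recs, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, marker_length: int, reference_seq: str,
                   n_reads: dict[str, int] | None = None) -> "PileupSet":
        ps = cls(marker_length=marker_length, reference_seq=reference_seq)
        if "count" not in df.columns:
            df = df.assign(count=1)
        for sid, grp in df.groupby("sample_id", sort=False):
            ps.add_observations(str(sid), grp["position"].to_numpy(),
                                grp["base"].tolist(), grp["count"].to_numpy())
        if n_reads:
            ps.n_reads.update({k: int(v) for k, v in n_reads.items()})
        else:
            for sid in ps.samples:
                ps.n_reads[sid] = int(ps.counts[sid].sum(axis=1).max(initial=0))
        return ps

    @classmethod
    def from_tsv(cls, path, marker_length: int, reference_seq: str) -> "PileupSet":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df, marker_length, reference_seq)


@dataclass
class ConsensusSequence:
    sample_id: str
    sequence: str
    n_reads: int
    mean_sccg_coverage: float | None = None
    frac_sccg_hlii: float | None = None
    qc_pass: bool | None = None
    qc_failures: list[str] = field(default_factory=list)

    @property
    def n_ambiguous(self) -> int:
        return self.sequence.count("N")


def call_consensus(pileup: PileupSet, min_depth: int = 5) -> dict[str, ConsensusSequence]:
    """Strict-majority consensus per position; depth < min_depth or ties -> 'N'.

    A sample with an empty pileup yields an all-N sequence with n_reads=0
    rather than an exception.
    """
    out: dict[str, ConsensusSequence] = {}
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    for sid in pileup.samples:
        c = pileup.counts[sid]
        depth = c.sum(axis=1)
        top = c.max(axis=1)
        winner = c.argmax(axis=1)
        n_top = (c == top[:, None]).sum(axis=1)
        seq = base_arr[winner].astype("U1")
        seq[(depth < min_depth) | (n_top > 1)] = "N"
        out[sid] = ConsensusSequence(
            sample_id=sid,
            sequence="".join(seq),
            n_reads=int(pileup.n_reads.get(sid, int(c.sum()))),
        )
    return out


def set_qc_metrics(consensus_set: dict[str, ConsensusSequence],
                   metrics: pd.DataFrame) -> dict[str, ConsensusSequence]:
    """Attach mean_sccg_coverage / frac_sccg_hlii from a per-sample table."""
    for sid, cons in consensus_set.items():
        if sid in metrics.index:
            cons.mean_sccg_coverage = float(metrics.loc[sid, "mean_sccg_coverage"])
            cons.frac_sccg_hlii = float(metrics.loc[sid, "frac_sccg_hlii"])
    return consensus_set


def qc_filter(consensus_set: dict[str, ConsensusSequence],
              min_reads: int = 2000,
              min_sccg_cov: float = 5.0,
              min_frac_hlii: float = 0.90) -> dict[str, ConsensusSequence]:
    """Flag each sample against the three inclusive quality gates.

    Gates: n_reads >= min_reads, mean_sccg_coverage >= min_sccg_cov,
    frac_sccg_hlii >= min_frac_hlii. Failures are enumerated by gate name.
    """
    for sid, cons in consensus_set.items():
        for metric in ("mean_sccg_coverage", "frac_sccg_hlii"):
            if getattr(cons, metric) is None:
                raise ValidationError(f"sample {sid!r}: missing QC metric {metric!r}")
        failures = []
        if cons.n_reads < min_reads:
            failures.append("min_reads")
        if cons.mean_sccg_coverage < min_sccg_cov:
            failures.append("min_sccg_cov")
        if cons.frac_sccg_hlii < min_frac_hlii:
            failures.append("min_frac_hlii")
        cons.qc_failures = failures
        cons.qc_pass = not failures
    n_fail = sum(1 for c in consensus_set.values() if not c.qc_pass)
    if n_fail:
        logger.info("QC: %d/%d samples failed", n_fail, len(consensus_set))
    return consensus_set


def consensus_metadata_frame(consensus_set: dict[str, ConsensusSequence]) -> pd.DataFrame:
    rows = {
        sid: {
            "n_rpoc1_reads": c.n_reads,
            "mean_sccg_coverage": c.mean_sccg_coverage,
            "frac_sccg_hlii": c.frac_sccg_hlii,
            "qc_pass": c.qc_pass,
            "qc_failures": ";".join(c.qc_failures),
            "n_ambiguous": c.n_ambiguous,
        }
        for sid, c in consensus_set.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


@dataclass
class SNPMatrix:
    """Samples x binary variant-allele indicators.

    Columns are (position, alt_base) pairs ordered by position then base;
    entry 1 means the sample's consensus carries that alternative allele.
    'N' in a consensus is encoded as 0 (allele absent) with the per-sample
    ambiguous-position count logged for diagnostics.
    """

    ids: list[str]
    columns: list[tuple[int, str]]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValidationError(
                f"SNP matrix shape {self.values.shape} != "
                f"({len(self.ids)}, {len(self.columns)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{pos}:{alt}" for pos, alt in self.columns]
        return pd.DataFrame(self.values, index=self.ids, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=True, index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SNPMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        columns = []
        for c in df.columns:
            pos, alt = c.split(":")
            columns.append((int(pos), alt))
        return cls(list(df.index.astype(str)), columns,
                   df.to_numpy(dtype=np.uint8))


def binarize_snps(consensus_set: dict[str, ConsensusSequence],
                  reference_seq: str,
                  only_qc_pass: bool = True) -> SNPMatrix:
    """Transform consensus sequences into a binary variant matrix.

    One column per (position, alt_base) observed in at least one sample where
    the consensus base differs from the reference and is not 'N'. Zero
    polymorphic positions yields a valid empty matrix.
    """
    ref = reference_seq.upper()
    items = [
        (sid, c) for sid, c in consensus_set.items()
        if (c.qc_pass or not only_qc_pass)
    ]
    if only_qc_pass and any(c.qc_pass is None for _, c in items):
        raise ValidationError("binarize_snps requires qc_filter to have run")
    ids = [sid for sid, _ in items]
    if not ids:
        return SNPMatrix(ids=[], columns=[], values=np.zeros((0, 0), dtype=np.uint8))
    L = len(ref)
    seqs = np.array([list(c.sequence.upper()) for _, c in items])
    if seqs.shape[1] != L:
        raise ValidationError("consensus length differs from reference length")
    ref_arr = np.array(list(ref))
    n_ambig = (seqs == "N").sum(axis=1)
    for sid, k in zip(ids, n_ambig):
        if k:
            logger.debug("sample %s: %d ambiguous positions encoded as 0", sid, k)
    variant = (seqs != ref_arr) & (seqs != "N")
    columns: list[tuple[int, str]] = []
    cols_data: list[np.ndarray] = []
    for pos in np.nonzero(variant.any(axis=0))[0]:
        alts = sorted(set(seqs[variant[:, pos], pos]))
        for alt in alts:
            columns.append((int(pos), alt))
            cols_data.append((seqs[:, pos] == alt).astype(np.uint8))
    values = (np.column_stack(cols_data) if cols_data
              else np.zeros((len(ids), 0), dtype=np.uint8))
    return SNPMatrix(ids=ids, columns=columns, values=values)
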
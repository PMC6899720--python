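"""In-memory containers for genotype data, population maps and distance matrices.

All per-locus arrays are indexed ``(locus, sample)``; missing genotypes are
``NaN``.  Locus identity is ``contig:pos`` (1-based VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOSAGES = np.array([0.0, 1.0, 2.0])


@dataclass
class GenotypeLikelihoodTable:
    """Per-locus x per-sample genotype-probability triplets.

    ``probs`` has shape (L, N, 3): probability of 0, 1 and 2 copies of the
    alternate allele given the read data.  A missing genotype is a NaN triplet.
    Present triplets sum to 1.
    """

    loci: np.ndarray        # (L,) locus ids, str
    samples: np.ndarray     # (N,) sample ids, str
    probs: np.ndarray       # (L, N, 3) float

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.probs = np.asarray(self.probs, dtype=float)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def expected_dosage(self) -> np.ndarray:
        """Posterior-mean alt dosage per genotype, shape (L, N); NaN if missing."""
        return self.probs @ DOSAGES

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample not in table: {e.args[0]!r}") from None

    def subset_samples(self, names) -> "GenotypeLikelihoodTable":
        idx = self.sample_indices(names)
        return GenotypeLikelihoodTable(self.loci, self.samples[idx], self.probs[:, idx, :])

    def subset_loci(self, mask_or_ids) -> "GenotypeLikelihoodTable":
        mask = _locus_mask(self.loci, mask_or_ids)
        return GenotypeLikelihoodTable(self.loci[mask], self.samples, self.probs[mask])


@dataclass
class CalledGenotypeTable:
    """Hard genotype calls (alt-allele dosage 0/1/2, NaN = missing) with quality."""

    loci: np.ndarray        # (L,)
    samples: np.ndarray     # (N,)
    dosage: np.ndarray      # (L, N) float in {0,1,2,NaN}
    gq: np.ndarray | None = None        # (L, N) genotype quality, NaN where missing
    contig: np.ndarray | None = None    # (L,) RAD contig per locus
    pos: np.ndarray | None = None       # (L,) 1-based position

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)

    def subset_samples(self, names) -> "CalledGenotypeTable":
        idx = self.sample_indices(names)
        gq = None if self.gq is None else self.gq[:, idx]
        return CalledGenotypeTable(self.loci, self.samples[idx], self.dosage[:, idx],
                                   gq, self.contig, self.pos)

    def subset_loci(self, mask_or_ids) -> "CalledGenotypeTable":
        mask = _locus_mask(self.loci, mask_or_ids)
        gq = None if self.gq is None else self.gq[mask]
        contig = None if self.contig is None else self.contig[mask]
        pos = None if self.pos is None else self.pos[mask]
        return CalledGenotypeTable(self.loci[mask], self.samples, self.dosage[mask],
                                   gq, contig, pos)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per locus from the calls (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=1) / 2.0


def _locus_mask(loci: np.ndarray, mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        return arr
    wanted = set(mask_or_ids)
    return np.array([l in wanted for l in loci], dtype=bool)


class PopulationMap:
    """sample -> (geographic site, host plant) assignments.

    A *population* is a (site, host) pair; a *sympatric site* carries both
    hosts of the configured host pair.
    """

    def __init__(self, frame: pd.DataFrame,
                 hosts: tuple[str, str] = ("Prunus", "Lonicera")) -> None:
        required = {"sample", "site", "host"}
        if not required.issubset(frame.columns):
            raise ValueError(f"popmap needs columns {sorted(required)}")
        unknown = set(frame["host"]) - set(hosts)
        if unknown:
            raise ValueError(f"unknown host labels {sorted(unknown)}; expected {hosts}")
        if frame["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in popmap")
        self.frame = frame.reset_index(drop=True)
        self.hosts = hosts

    @classmethod
    def from_tsv(cls, path, hosts: tuple[str, str] = ("Prunus", "Lonicera")) -> "PopulationMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        frame.columns = ["sample", "site", "host"][: len(frame.columns)]
        return cls(frame, hosts)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> np.ndarray:
        return self.frame["sample"].to_numpy()

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.frame["site"]))

    def populations(self) -> list[tuple[str, str]]:
        """(site, host) pairs in first-appearance order."""
        seen = dict.fromkeys(zip(self.frame["site"], self.frame["host"]))
        return list(seen)

    def sympatric_sites(self) -> list[str]:
        out = []
        for site in self.sites:
            present = set(self.frame.loc[self.frame["site"] == site, "host"])
            if set(self.hosts) <= present:
                out.append(site)
        return out

    def samples_for(self, site: str | None = None, host: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.frame), dtype=bool)
        if site is not None:
            mask &= (self.frame["site"] == site).to_numpy()
        if host is not None:
            mask &= (self.frame["host"] == host).to_numpy()
        return self.frame.loc[mask, "sample"].to_numpy()

    def pop_labels(self, samples) -> np.ndarray:
        """'site:host' label per sample, aligned with ``samples``."""
        lut = {r["sample"]: f"{r['site']}:{r['host']}" for _, r in self.frame.iterrows()}
        return np.array([lut[s] for s in samples], dtype=object)

    def __contains__(self, sample: str) -> bool:
        return sample in set(self.frame["sample"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    def upper(self) -> np.ndarray:
        """Off-diagonal upper triangle as a condensed vector."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])
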
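"""Synthetic proteins with planted methylation signal.

The generator emulates, with controllable strength, the three signals a
real methylation training set carries around positive sites:

* a sequence motif — by default glycine planted at offsets −1, +1 and +2
  of each positive center, mimicking the glycine-rich (RGG-like) context
  of methylarginine;
* a depression of side-chain van der Waals volume near positives,
  produced by resampling non-motif flank residues (|offset| ≤ 3) from
  the small-volume half of the property table;
* elevated solvent exposure: per-residue ASA is drawn from a truncated
  normal whose mean is class-specific (residues within the window of a
  positive center use the positive mean).

Background residues are uniform over the 20 standard amino acids — the
simplest exchangeable null, so that with all signals switched off the
positive and negative classes are statistically indistinguishable.
Everything is reproducible: equal seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .io import (
    STANDARD_RESIDUES,
    ProteinRecord,
    SiteInstance,
    read_property_table,
    write_asa,
    write_fasta,
    write_sites,
)

#: Offsets whose residues may be VDWV-resampled around a positive center.
VDWV_NEIGHBORHOOD = 3


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_proteins: int = 120
    length_range: tuple[int, int] = (500, 700)
    residue_type: str = "R"
    n_positives: int = 300
    #: per-offset probability that the motif residue is actually planted
    p_signal: float = 1.0
    #: offset → residue to plant around each positive center
    motif_spec: dict[int, str] = field(
        default_factory=lambda: {-1: "G", 1: "G", 2: "G"}
    )
    #: probability of resampling each non-motif flank residue (|offset|<=3)
    #: from the small-volume half of the VDWV table
    vdwv_shift: float = 0.5
    asa_positive_mean: float = 45.0
    asa_negative_mean: float = 30.0
    asa_sd: float = 10.0
    #: window half-width used for the ASA neighborhood around positives
    L: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_signal <= 1.0:
            raise SyntheticError("p_signal must lie in [0, 1]")
        if not 0.0 <= self.vdwv_shift <= 1.0:
            raise SyntheticError("vdwv_shift must lie in [0, 1]")
        if self.residue_type not in ("R", "K"):
            raise SyntheticError("residue_type must be 'R' or 'K'")
        if self.n_proteins < 1 or self.n_positives < 1:
            raise SyntheticError("n_proteins and n_positives must be >= 1")
        for offset, residue in self.motif_spec.items():
            if residue not in STANDARD_RESIDUES:
                raise SyntheticError(f"motif residue {residue!r} is not standard")
            if offset == 0 or abs(offset) > VDWV_NEIGHBORHOOD:
                raise SyntheticError(
                    f"motif offset {offset} must be nonzero and within "
                    f"±{VDWV_NEIGHBORHOOD} of the center"
                )


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    sites: list[SiteInstance]  # positive annotations only
    truth: list[SiteInstance]  # every center, labelled
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit proteins.fasta, sites.tsv, asa.tsv and truth.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "sites": out / "sites.tsv",
            "asa": out / "asa.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_sites(self.sites, paths["sites"])
        write_asa(self.proteins, paths["asa"])
        write_sites(self.truth, paths["truth"])
        return paths


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int):
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full synthetic dataset described by ``config``."""
    rng = np.random.default_rng(config.seed)
    table = read_property_table()
    median_vdwv = float(np.median(list(table.vdwv_of.values())))
    small_pool = sorted(
        aa
        for aa, v in table.vdwv_of.items()
        if v <= median_vdwv and aa not in ("R", "K")
    )

    alphabet = np.array(list(STANDARD_RESIDUES))
    sequences: list[np.ndarray] = []
    for _ in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        sequences.append(rng.choice(alphabet, size=length))

    # Positive centers are drawn uniformly from all residue_type positions.
    # The only spacing constraint is that two positives must lie further
    # apart than the widest motif offset, so that planting one positive's
    # flanks can never overwrite another positive center.  That constraint
    # leaves no trace in any window-encodable feature (a positive may still
    # have background R/K anywhere in its flanks), keeping the p_signal=0
    # configuration an exact null.
    min_sep = max((abs(o) for o in config.motif_spec), default=1) + 1
    candidates: list[tuple[int, int]] = []  # (protein index, 0-based pos)
    for pi, seq in enumerate(sequences):
        candidates.extend(
            (pi, int(pos)) for pos in np.flatnonzero(seq == config.residue_type)
        )
    positive_centers: set[tuple[int, int]] = set()
    for i in rng.permutation(len(candidates)):
        pi, pos = candidates[i]
        if any(
            pj == pi and abs(qos - pos) < min_sep for pj, qos in positive_centers
        ):
            continue
        positive_centers.add((pi, pos))
        if len(positive_centers) == config.n_positives:
            break
    if len(positive_centers) < config.n_positives:
        raise SyntheticError(
            f"requested {config.n_positives} positives but only "
            f"{len(positive_centers)} {config.residue_type} centers are available"
        )

    # plant the motif and the small-volume neighborhood around positives
    for pi, pos in sorted(positive_centers):
        seq = sequences[pi]
        for offset, residue in sorted(config.motif_spec.items()):
            idx = pos + offset
            if 0 <= idx < len(seq) and rng.random() < config.p_signal:
                seq[idx] = residue
        if config.vdwv_shift > 0:
            for offset in range(-VDWV_NEIGHBORHOOD, VDWV_NEIGHBORHOOD + 1):
                idx = pos + offset
                if offset == 0 or offset in config.motif_spec:
                    continue
                # never resample another positive center's residue
                if (pi, idx) in positive_centers:
                    continue
                if 0 <= idx < len(seq) and rng.random() < config.vdwv_shift:
                    seq[idx] = rng.choice(small_pool)

    # ASA tracks: background mean everywhere, positive mean near positives
    proteins: list[ProteinRecord] = []
    for pi, seq in enumerate(sequences):
        asa = _truncnorm(rng, config.asa_negative_mean, config.asa_sd, len(seq))
        if config.asa_positive_mean != config.asa_negative_mean:
            near = np.zeros(len(seq), dtype=bool)
            for pj, pos in sorted(positive_centers):
                if pj == pi:
                    lo = max(0, pos - config.L)
                    hi = min(len(seq), pos + config.L + 1)
                    near[lo:hi] = True
            if near.any():
                asa[near] = _truncnorm(
                    rng, config.asa_positive_mean, config.asa_sd, int(near.sum())
                )
        proteins.append(
            ProteinRecord(
                id=f"synth{pi:04d}",
                sequence="".join(seq),
                asa=[float(v) for v in asa],
            )
        )

    # sites: the planted positives; truth: every center, labelled.
    # motif planting only overwrites non-center positions, but may remove
    # background R/K occurrences, so centers are re-enumerated here.
    sites, truth = [], []
    for pi, protein in enumerate(proteins):
        for idx, residue in enumerate(protein.sequence):
            if residue != config.residue_type:
                continue
            label = "positive" if (pi, idx) in positive_centers else "negative"
            site = SiteInstance(
                protein.id, idx + 1, residue, label, source="synthetic"
            )
            truth.append(site)
            if label == "positive":
                sites.append(site)
    assert len(sites) == config.n_positives
    return SyntheticDataset(proteins=proteins, sites=sites, truth=truth, config=config)


#: Fixture profiles: `small` for fast unit tests, `standard` emulates the
#: scale of a curated methylarginine training set (hundreds of positives,
#: thousands of background centers).
PROFILES = {
    "small": dict(n_proteins=30, length_range=(150, 250), n_positives=50),
    "standard": dict(n_proteins=120, length_range=(500, 700), n_positives=300),
}


def make_fixture(
    profile: str = "small",
    signal: bool = True,
    seed: int = 0,
    residue_type: str = "R",
    out_dir: Optional[str | Path] = None,
) -> SyntheticDataset:
    """A ready-made dataset under one of the named profiles.

    ``signal=False`` switches every planted difference off (no motif, no
    volume shift, equal ASA means), giving an exchangeable null.
    """
    if profile not in PROFILES:
        raise SyntheticError(f"unknown profile {profile!r}")
    kwargs = dict(PROFILES[profile])
    if not signal:
        kwargs.update(p_signal=0.0, vdwv_shift=0.0, asa_positive_mean=30.0)
    dataset = generate(
        SyntheticConfig(seed=seed, residue_type=residue_type, **kwargs)
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
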
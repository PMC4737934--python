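"""Droplet-level simulator for emulsion fusion-PCR sequencing runs.

The generative model mirrors the structure of a real spike-in experiment:

* droplets are polydisperse spheres (truncated lognormal diameters,
  5-30 μm, median 10 μm);
* environmental cells load into droplets as Poisson(cell λ), each cell a
  taxon drawn by relative abundance and retained only if permeabilized;
* soluble barcode molecules load per droplet as Poisson with mean set by
  the barcode concentration and each droplet's own volume;
* disjoint droplet subsets carry synthetic control beads — negative beads
  with a mock-16S amplicon only, positive beads with mock-16S plus a
  mock-target amplicon;
* fusion PCR inside each droplet emits full fusion amplicons
  [F1|target or barcode|bridge|16S] only when a target-side template and a
  16S template co-occur, plus partially fused single-sided amplicons and
  within-droplet single-crossover chimeras at configurable rates, with a
  lognormal per-droplet amplification skew;
* paired-end reads of fixed length are drawn from each amplicon with
  substitution errors and synthetic quality strings, and every read is
  recorded in a ground-truth table.

All randomness flows from a single ``numpy`` generator seeded by
``SimConfig.seed``; identical configurations produce byte-identical FASTQ
and truth files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from epicpcr.construct import FusionConstructSpec, DEFAULT_CONSTRUCT
from epicpcr.emulsion import molecules_per_droplet
from epicpcr.iupac import expansion, reverse_complement, validate_iupac

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Diameter model: lognormal about a 10 μm median, truncated to the 5-30 μm
# range reported for polyacrylamide beads.
_DIAM_MEDIAN_UM = 10.0
_DIAM_LOG_SD = 0.30
_DIAM_RANGE_UM = (5.0, 30.0)

_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Chloroflexi",
    "Cyanobacteria",
    "Planctomycetes",
    "Verrucomicrobia",
)


@dataclass(frozen=True)
class Taxon:
    """One community member: a 16S-like sequence, optionally a target gene."""

    taxon_id: str
    lineage: tuple[str, ...]
    ssu_seq: str
    abundance: float
    has_target: bool = False
    target_seq: str | None = None
    permeabilization_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.has_target and not self.target_seq:
            raise ValueError(f"{self.taxon_id}: has_target requires target_seq")
        if not 0.0 <= self.permeabilization_prob <= 1.0:
            raise ValueError("permeabilization_prob must be in [0, 1]")


@dataclass(frozen=True)
class ControlBead:
    """Synthetic spike-in bead: mock-16S, and a mock target if positive."""

    control_id: str
    kind: str  # "positive" | "negative"
    ssu_seq: str
    target_seq: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("positive", "negative"):
            raise ValueError("kind must be 'positive' or 'negative'")
        if self.kind == "positive" and not self.target_seq:
            raise ValueError("positive control needs a mock target sequence")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of one simulated sequencing run.

    ``assay`` selects what the target side of the fusion is: ``target16s``
    fuses the functional gene carried by target-positive taxa (and the
    positive-control mock target); ``barcode16s`` fuses a random barcode
    molecule loaded at ``barcode_conc``.
    """

    seed: int = 0
    n_droplets: int = 10_000
    cell_lambda: float = 0.0287
    barcode_conc: float = 10e-12  # molar; 10 pM ~ 3 molecules/10 μm droplet
    pos_ctrl_frac: float = 0.01
    neg_ctrl_frac: float = 0.01
    fusion_efficiency: float = 0.9
    partial_fusion_rate: float = 0.10
    chimera_rate: float = 0.02
    amp_log_sd: float = 1.0
    subst_error_rate: float = 0.001
    indel_error_rate: float = 0.0
    degraded_frac: float = 0.05
    mean_reads_per_droplet: float = 15.0
    leakage_rate: float = 0.0
    assay: str = "target16s"
    sample_id: str = "S1"
    sample_barcode: str = "ACGTGACT"

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        for name in (
            "pos_ctrl_frac",
            "neg_ctrl_frac",
            "fusion_efficiency",
            "partial_fusion_rate",
            "chimera_rate",
            "subst_error_rate",
            "indel_error_rate",
            "degraded_frac",
            "leakage_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pos_ctrl_frac + self.neg_ctrl_frac > 1.0:
            raise ValueError("control droplet fractions sum to more than 1")
        if self.cell_lambda < 0 or self.barcode_conc < 0:
            raise ValueError("loading parameters must be >= 0")
        if self.assay not in ("target16s", "barcode16s"):
            raise ValueError("assay must be 'target16s' or 'barcode16s'")
        validate_iupac(self.sample_barcode, "sample_barcode")


@dataclass
class SimAmplicon:
    """One amplicon species in a droplet, with an emission weight."""

    droplet_id: int
    klass: str  # "full_fusion" | "partial" | "chimera"
    seq: str
    target_source: str | None
    ssu_source: str | None
    barcode: str | None
    weight: float
    parents: tuple[str, str] | None = None  # chimeras: the two parent classes


@dataclass
class SimReadPair:
    read_id: str
    sample_id: str
    r1_seq: str
    r1_qual: np.ndarray
    r2_seq: str
    r2_qual: np.ndarray


@dataclass
class SimResult:
    """A simulated run: occupancy, amplicons, reads and per-read truth."""

    config: SimConfig
    construct: FusionConstructSpec
    community: list[Taxon]
    controls: list[ControlBead]
    droplets: pd.DataFrame
    amplicons: list[SimAmplicon]
    read_pairs: list[SimReadPair]
    truth: pd.DataFrame

    def write_fastq(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p1, p2 = out_dir / "R1.fastq.gz", out_dir / "R2.fastq.gz"
        with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
            for rp in self.read_pairs:
                f1.write(_fastq_record(rp.read_id, rp.r1_seq, rp.r1_qual))
                f2.write(_fastq_record(rp.read_id, rp.r2_seq, rp.r2_qual))
        return p1, p2

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        self.truth.to_csv(path, sep="\t", index=False)
        return path

    def write_community_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for t in self.community:
                fh.write(f">{t.taxon_id} {';'.join(t.lineage)}\n{t.ssu_seq}\n")
        return path

    def write_controls_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for c in self.controls:
                fh.write(f">{c.control_id} {c.kind}\n{c.ssu_seq}\n")
        return path


def _fastq_record(rid: str, seq: str, qual: np.ndarray) -> str:
    qstr = (qual.astype(np.uint8) + 33).tobytes().decode("ascii")
    return f"@{rid}\n{seq}\n+\n{qstr}\n"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _instantiate(motif: str, rng: np.random.Generator | None = None) -> str:
    """Pick one concrete expansion of a degenerate motif (first base if no rng)."""
    out = []
    for code in motif:
        bases = sorted(expansion(code))
        out.append(bases[0] if rng is None else rng.choice(bases))
    return "".join(out)


def validate_community(community: Sequence[Taxon], construct: FusionConstructSpec) -> None:
    total = sum(t.abundance for t in community)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"community abundances sum to {total}, expected 1")
    anchor = _anchor_regexless_counter(construct.anchor_motif)
    for t in community:
        n = anchor(t.ssu_seq)
        if n != 1:
            raise ValueError(f"{t.taxon_id}: anchor motif occurs {n} times, expected 1")


def _anchor_regexless_counter(motif: str):
    """IUPAC-aware exact occurrence counter for the anchor motif."""
    from epicpcr.iupac import encode

    m = encode(motif)

    def count(seq: str) -> int:
        s = encode(seq)
        if len(s) < len(m):
            return 0
        win = np.lib.stride_tricks.sliding_window_view(s, len(m))
        return int(((win & m) != 0).all(axis=1).sum())

    return count


def make_default_community(
    n_taxa: int = 12,
    frac_with_target: float = 0.25,
    seed: int = 0,
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
    v4_len: int = 130,
    target_len: int = 60,
    permeabilization_prob: float = 0.9,
    dirichlet_alpha: float = 1.0,
) -> list[Taxon]:
    """Random community of 16S-like sequences with one V4 anchor each.

    Exactly ``round(n_taxa * frac_with_target)`` taxa carry a target gene.
    Abundances come from a symmetric Dirichlet draw. Every 16S sequence is
    anchor + random V4 + the reverse complement of the R2 priming site, so
    a fused read carries ``v4_len`` >= ``trim_len`` trimmable bases.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not 0.0 <= frac_with_target <= 1.0:
        raise ValueError("frac_with_target must be in [0, 1]")
    if v4_len < construct.trim_len:
        raise ValueError("v4_len must be >= construct.trim_len")
    rng = np.random.default_rng(seed)
    anchor = _instantiate(construct.anchor_motif)
    rc_r2 = reverse_complement(_instantiate(construct.r2))
    counter = _anchor_regexless_counter(construct.anchor_motif)

    n_target = round(n_taxa * frac_with_target)
    target_idx = set(rng.choice(n_taxa, size=n_target, replace=False).tolist())
    abundances = rng.dirichlet(np.full(n_taxa, dirichlet_alpha))

    taxa: list[Taxon] = []
    for i in range(n_taxa):
        while True:
            ssu = anchor + _random_seq(rng, v4_len) + rc_r2
            if counter(ssu) == 1:
                break
        has_target = i in target_idx
        taxa.append(
            Taxon(
                taxon_id=f"taxon{i:03d}",
                lineage=(_PHYLA[i % len(_PHYLA)], f"genus{i:03d}"),
                ssu_seq=ssu,
                abundance=float(abundances[i]),
                has_target=has_target,
                target_seq=_random_seq(rng, target_len) if has_target else None,
                permeabilization_prob=permeabilization_prob,
            )
        )
    validate_community(taxa, construct)
    return taxa


def make_default_controls(
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
    seed: int = 424242,
    v4_len: int = 130,
    target_len: int = 60,
) -> list[ControlBead]:
    """Positive (mock-16S + mock-target) and negative (mock-16S) beads.

    Generated from a fixed internal seed so the control sequences are
    stable reference points across simulations.
    """
    rng = np.random.default_rng(seed)
    anchor = _instantiate(construct.anchor_motif)
    rc_r2 = reverse_complement(_instantiate(construct.r2))
    pos_ssu = anchor + _random_seq(rng, v4_len) + rc_r2
    neg_ssu = anchor + _random_seq(rng, v4_len) + rc_r2
    mock_target = _random_seq(rng, target_len)
    return [
        ControlBead("ctrl_pos", "positive", pos_ssu, mock_target),
        ControlBead("ctrl_neg", "negative", neg_ssu),
    ]


def simulate_droplets(
    community: Sequence[Taxon],
    config: SimConfig,
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw droplet diameters, cell loads, barcode loads and control beads.

    Returns one row per droplet: ``droplet_id``, ``diameter`` (μm),
    ``taxa`` (tuple of permeabilized taxon ids), ``n_barcodes``,
    ``control`` (control_id or None).
    """
    validate_community(community, construct)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_droplets

    # truncated lognormal diameters
    diam = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(np.log(_DIAM_MEDIAN_UM), _DIAM_LOG_SD, size=todo.size)
        ok = (draw >= _DIAM_RANGE_UM[0]) & (draw <= _DIAM_RANGE_UM[1])
        diam[todo[ok]] = draw[ok]
        todo = todo[~ok]

    n_cells = rng.poisson(config.cell_lambda, size=n)

    # barcode Poisson mean scales with each droplet's volume (d^3)
    lam10 = molecules_per_droplet(config.barcode_conc, _DIAM_MEDIAN_UM)
    lam_bc = lam10 * (diam / _DIAM_MEDIAN_UM) ** 3
    n_barcodes = rng.poisson(lam_bc)

    # disjoint control-bead droplets; a bead displaces environmental cells
    n_pos = int(round(config.pos_ctrl_frac * n))
    n_neg = int(round(config.neg_ctrl_frac * n))
    ctrl_idx = rng.choice(n, size=n_pos + n_neg, replace=False)
    control = np.full(n, None, dtype=object)
    control[ctrl_idx[:n_pos]] = "ctrl_pos"
    control[ctrl_idx[n_pos:]] = "ctrl_neg"
    n_cells[ctrl_idx] = 0

    abund = np.array([t.abundance for t in community])
    perm = np.array([t.permeabilization_prob for t in community])
    ids = [t.taxon_id for t in community]

    taxa_col: list[tuple[str, ...]] = [()] * n
    for i in np.flatnonzero(n_cells):
        drawn = rng.choice(len(ids), size=n_cells[i], p=abund)
        kept = drawn[rng.random(drawn.size) < perm[drawn]]
        taxa_col[i] = tuple(ids[j] for j in kept)

    return pd.DataFrame(
        {
            "droplet_id": np.arange(n),
            "diameter": diam,
            "taxa": taxa_col,
            "n_barcodes": n_barcodes,
            "control": control,
        }
    )


def _crossover(a: str, b: str, k: int) -> str:
    return a[:k] + b[k:]


def simulate_fusion(
    droplet: pd.Series | dict,
    construct: FusionConstructSpec,
    config: SimConfig,
    community_map: dict[str, Taxon],
    control_map: dict[str, ControlBead],
    rng: np.random.Generator,
) -> list[SimAmplicon]:
    """Emit the amplicon species of one droplet.

    Full fusions require a target-side template and a 16S template in the
    same droplet and each candidate pairing succeeds with
    ``fusion_efficiency``. Partial (one-sided) amplicons and within-droplet
    chimeras are emitted at their configured rates; all weights share the
    droplet's lognormal amplification factor.
    """
    did = int(droplet["droplet_id"])
    taxa = [community_map[t] for t in droplet["taxa"]]
    ctrl = control_map.get(droplet["control"]) if droplet["control"] else None

    ssu_templates: list[tuple[str, str]] = [(t.taxon_id, t.ssu_seq) for t in taxa]
    if ctrl is not None:
        ssu_templates.append((ctrl.control_id, ctrl.ssu_seq))

    target_templates: list[tuple[str, str, str | None]] = []  # (source, core, barcode)
    if config.assay == "target16s":
        for t in taxa:
            if t.has_target:
                target_templates.append((t.taxon_id, t.target_seq, None))
        if ctrl is not None and ctrl.kind == "positive":
            target_templates.append((ctrl.control_id, ctrl.target_seq, None))
    else:  # barcode16s
        for _ in range(int(droplet["n_barcodes"])):
            bc = _random_seq(rng, construct.barcode_len)
            target_templates.append(("barcode", bc, bc))

    if not ssu_templates and not target_templates:
        return []

    skew = float(rng.lognormal(0.0, config.amp_log_sd))
    out: list[SimAmplicon] = []

    fulls: list[SimAmplicon] = []
    for src, core, bc in target_templates:
        for ssu_src, ssu in ssu_templates:
            if rng.random() >= config.fusion_efficiency:
                continue
            seq = construct.f1 + core + construct.bridge + ssu
            fulls.append(
                SimAmplicon(did, "full_fusion", seq, src, ssu_src, bc, skew)
            )
    out.extend(fulls)

    # one-sided (partial) amplicons escape the blocking primers only in
    # droplets where the fusion reaction engaged (a 16S template present);
    # isolated target/barcode molecules never reach exponential phase
    if config.partial_fusion_rate > 0 and ssu_templates:
        w = config.partial_fusion_rate * skew
        for src, core, bc in target_templates:
            seq = construct.f1 + core + construct.bridge
            out.append(SimAmplicon(did, "partial", seq, src, None, bc, w))
        for ssu_src, ssu in ssu_templates:
            out.append(SimAmplicon(did, "partial", ssu, None, ssu_src, None, w))

    if config.chimera_rate > 0 and len(fulls) >= 2:
        # one chimera species per droplet with >=2 equal-length parents;
        # the breakpoint is uniform over positions that give a recombinant
        # distinct from both parents (elsewhere the product IS a parent)
        pairs = [
            (i, j)
            for i in range(len(fulls))
            for j in range(len(fulls))
            if i != j and len(fulls[i].seq) == len(fulls[j].seq)
        ]
        if pairs:
            i, j = pairs[rng.integers(len(pairs))]
            a, b = fulls[i], fulls[j]
            aa = np.frombuffer(a.seq.encode("ascii"), dtype=np.uint8)
            bb = np.frombuffer(b.seq.encode("ascii"), dtype=np.uint8)
            diffs = np.flatnonzero(aa != bb)
            if diffs.size >= 2:
                k = int(rng.integers(diffs[0] + 1, diffs[-1] + 1))
                out.append(
                    SimAmplicon(
                        did,
                        "chimera",
                        _crossover(a.seq, b.seq, k),
                        a.target_source,
                        b.ssu_source,
                        a.barcode,
                        config.chimera_rate * (a.weight + b.weight) / 2.0,
                        parents=(a.ssu_source or "", b.ssu_source or ""),
                    )
                )
    return out


def _qualities(
    rng: np.random.Generator, length: int, degraded: bool
) -> np.ndarray:
    """Synthetic Phred scores: high plateau with 3' decay, or degraded flat."""
    if degraded:
        q = rng.integers(9, 14, size=length)
    else:
        base = np.full(length, 38.0)
        tail = length // 3
        if tail:
            base[-tail:] -= np.linspace(0, 10, tail)
        q = base + rng.integers(-2, 3, size=length)
    return np.clip(q, 2, 41).astype(np.int16)


def _add_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_reads(
    amplicons: Sequence[SimAmplicon],
    construct: FusionConstructSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[SimReadPair], pd.DataFrame]:
    """Draw paired-end reads from amplicons and record per-read truth.

    Read-pair counts per amplicon are Poisson(mean_reads_per_droplet x
    weight). R1 is the sample barcode followed by the first ``read_len``
    amplicon bases; R2 is the first ``read_len`` bases of the reverse
    complement. Substitution errors apply to amplicon-derived bases.
    """
    pairs: list[SimReadPair] = []
    rows: list[dict] = []
    idx = 0
    for amp in amplicons:
        if len(amp.seq) < len(construct.f1):
            raise ValueError("amplicon shorter than the forward primer")
        n_reads = rng.poisson(config.mean_reads_per_droplet * amp.weight)
        if n_reads == 0:
            continue
        span = min(construct.read_len, len(amp.seq))
        rc = reverse_complement(amp.seq)
        for _ in range(n_reads):
            rid = f"read{idx:07d}"
            idx += 1
            degraded = bool(rng.random() < config.degraded_frac)
            r1_core = _add_substitutions(rng, amp.seq[:span], config.subst_error_rate)
            r2_core = _add_substitutions(rng, rc[:span], config.subst_error_rate)
            r1 = config.sample_barcode + r1_core
            pairs.append(
                SimReadPair(
                    read_id=rid,
                    sample_id=config.sample_id,
                    r1_seq=r1,
                    r1_qual=np.concatenate(
                        [
                            np.full(len(config.sample_barcode), 38, dtype=np.int16),
                            _qualities(rng, span, degraded),
                        ]
                    ),
                    r2_seq=r2_core,
                    r2_qual=_qualities(rng, span, degraded),
                )
            )
            rows.append(
                {
                    "read_id": rid,
                    "sample_id": config.sample_id,
                    "droplet_id": amp.droplet_id,
                    "class": amp.klass,
                    "target_source": amp.target_source,
                    "ssu_source": amp.ssu_source,
                    "barcode": amp.barcode,
                    "degraded": degraded,
                    "leaked": getattr(amp, "leaked", False),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "sample_id",
            "droplet_id",
            "class",
            "target_source",
            "ssu_source",
            "barcode",
            "degraded",
            "leaked",
        ],
    )
    return pairs, truth


def simulate_experiment(
    community: Sequence[Taxon],
    config: SimConfig,
    controls: Sequence[ControlBead] | None = None,
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
) -> SimResult:
    """Run the full generative model: droplets -> amplicons -> reads + truth."""
    if controls is None:
        controls = make_default_controls(construct)
    rng = np.random.default_rng(config.seed)
    droplets = simulate_droplets(community, config, construct, rng)
    community_map = {t.taxon_id: t for t in community}
    control_map = {c.control_id: c for c in controls}

    amplicons: list[SimAmplicon] = []
    # droplets without any 16S template emit nothing (no fusion partner,
    # and one-sided pieces require an engaged reaction)
    busy = droplets[(droplets["taxa"].str.len() > 0) | droplets["control"].notna()]
    for _, row in busy.iterrows():
        amplicons.extend(
            simulate_fusion(row, construct, config, community_map, control_map, rng)
        )

    if config.leakage_rate > 0 and amplicons:
        _inject_leakage(amplicons, droplets, community_map, control_map, construct, config, rng)

    read_pairs, truth = generate_reads(amplicons, construct, config, rng)
    return SimResult(
        config=config,
        construct=construct,
        community=list(community),
        controls=list(controls),
        droplets=droplets,
        amplicons=amplicons,
        read_pairs=read_pairs,
        truth=truth,
    )


def _inject_leakage(
    amplicons: list[SimAmplicon],
    droplets: pd.DataFrame,
    community_map: dict[str, Taxon],
    control_map: dict[str, ControlBead],
    construct: FusionConstructSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Cross-droplet contamination: swap the 16S side of some full fusions.

    Models unspecific background by re-pairing a fusion's target side with
    a 16S template drawn from the whole emulsion (weighted by droplet
    occupancy), breaking single-droplet specificity.
    """
    pool: list[str] = []
    for _, row in droplets.iterrows():
        pool.extend(row["taxa"])
        if row["control"]:
            pool.append(row["control"])
    if not pool:
        return
    for amp in amplicons:
        if amp.klass != "full_fusion" or rng.random() >= config.leakage_rate:
            continue
        src = pool[rng.integers(len(pool))]
        ssu = (
            control_map[src].ssu_seq
            if src in control_map
            else community_map[src].ssu_seq
        )
        prefix_len = len(amp.seq) - len(
            community_map[amp.ssu_source].ssu_seq
            if amp.ssu_source in community_map
            else control_map[amp.ssu_source].ssu_seq
        )
        amp.seq = amp.seq[:prefix_len] + ssu
        amp.ssu_source = src
        amp.leaked = True  # type: ignore[attr-defined]
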
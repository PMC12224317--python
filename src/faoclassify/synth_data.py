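"""Seeded generators for every input the pipeline consumes.

Three generators emulate the three experimental data streams:

* stopped-flow trace sets — noiseless mechanism simulations plus i.i.d.
  Gaussian absorbance noise (default sigma 0.002 AU, a plausible
  photometric noise floor; no dead-time or photobleaching artifacts);
* annotated genome records — contigs with planted FAO genes in each of the
  four operon configurations (including a fused FAO-CytC polypeptide),
  surrounded by decoy genes, written as GenBank flat files with a truth
  table;
* character-mapped trees — Yule trees whose tips carry a four-state
  character evolved under the equal-rates Markov model, with the full true
  history recorded.

Synthetic protein sequences are random over the 20-letter alphabet with the
diagnostic motifs planted (or scrubbed) explicitly; no attempt is made to
mimic real FAO composition.  Every generator is reproducible from its
arguments and seed alone.
"""

from __future__ import annotations

import json
import math
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetic_core import (
    KineticScheme,
    MixState,
    SpectralModel,
    Trace,
    absorbance_trace,
    simulate_mechanism,
)
from .signpost_scan import GeneRecord

__all__ = [
    "SynthConfig",
    "gen_stopped_flow_dataset",
    "gen_synthetic_operons",
    "gen_character_tree",
    "cytc_time_grid",
    "o2_time_grid",
    "TAT_SIGNAL",
    "SEC_SIGNAL",
]

#: planted twin-arginine signal (motif TRRNF at position 3, h-region follows)
TAT_SIGNAL = "MSTRRNFLKAAVLLGALAG"
#: PelB-style Sec signal (basic n-region, hydrophobic core, AxA cleavage)
SEC_SIGNAL = "MKYLLPTAAAGLLLLAAQPAMA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Knobs shared by the generators; a fixed seed fixes every output."""

    seed: int = 0
    noise_sigma: float = 0.002          # AU
    intergenic_gap: tuple[int, int] = (50, 400)   # bp
    decoys_per_contig: int = 2
    n_tips: int = 32
    birth_rate: float = 1.0
    mk_rate: float = 0.5


# ---------------------------------------------------------------------------
# stopped-flow traces


def o2_time_grid(scheme: KineticScheme, conc: float, n: int = 400) -> np.ndarray:
    """Linear grid spanning ~8 pseudo-first-order lifetimes of the O2 step."""
    t_end = 8.0 / (scheme.k_o2 * conc)
    return np.linspace(0.0, t_end, n)


def cytc_time_grid(scheme: KineticScheme, conc: float, n: int = 400) -> np.ndarray:
    """Log-spaced grid resolving both CytC phases (fast phase can be >10x
    the slow one, so early sampling is geometric)."""
    k_slow = scheme.k2f if scheme.k2f > 0 else scheme.k1f
    t_end = 10.0 / (k_slow * conc)
    return np.concatenate([[0.0], np.geomspace(t_end * 1e-5, t_end, n - 1)])


def gen_stopped_flow_dataset(
    scheme: KineticScheme,
    enzyme_conc: float,
    oxidant_ladder: list[float],
    sigma: float = 0.002,
    seed: int = 0,
    oxidant: str = "cytc",
    spec: SpectralModel | None = None,
    out_dir: str | Path | None = None,
    n_points: int = 400,
):
    """One trace per oxidant concentration from the mechanism simulator,
    plus additive Gaussian noise.

    Returns ``(traces, manifest)`` where the manifest is a DataFrame
    recording the ground-truth constants; with ``out_dir`` the traces are
    also written as CSV files with a JSON sidecar each and a manifest CSV.
    """
    import pandas as pd

    if not oxidant_ladder:
        raise ValueError("oxidant ladder must be nonempty")
    if oxidant not in ("o2", "cytc"):
        raise ValueError("oxidant must be 'o2' or 'cytc'")
    if spec is None:
        spec = SpectralModel()
    rng = np.random.default_rng(seed)
    wavelength = 450 if oxidant == "o2" else 550

    traces: list[Trace] = []
    rows = []
    for i, conc in enumerate(oxidant_ladder):
        if oxidant == "o2":
            init = MixState(e_flh2=enzyme_conc, o2=conc)
            grid = o2_time_grid(scheme, conc, n_points)
        else:
            init = MixState(e_flh2=enzyme_conc, c_ox=conc)
            grid = cytc_time_grid(scheme, conc, n_points)
        traj = simulate_mechanism(scheme, init, grid)
        trace = absorbance_trace(traj, spec, wavelength)
        if sigma > 0:
            trace.absorbance = trace.absorbance + rng.normal(0.0, sigma,
                                                             trace.absorbance.size)
        trace.label = f"trace_{i:02d}"
        traces.append(trace)
        rows.append({
            "trace_id": trace.label,
            "oxidant": oxidant,
            "oxidant_conc_M": conc,
            "wavelength_nm": wavelength,
            "enzyme_conc_M": enzyme_conc,
            "true_k_o2": scheme.k_o2,
            "true_k1f": scheme.k1f,
            "true_k2f": scheme.k2f,
            "noise_sigma_AU": sigma,
            "seed": seed,
        })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trace, row in zip(traces, rows):
            path = out / f"{trace.label}.csv"
            pd.DataFrame({"time_s": trace.time,
                          "absorbance_AU": trace.absorbance}).to_csv(path, index=False)
            sidecar = dict(row)
            sidecar["scheme"] = {"k_o2": scheme.k_o2, "k1f": scheme.k1f,
                                 "k2f": scheme.k2f, "K1": scheme.K1, "K2": scheme.K2}
            (out / f"{trace.label}.json").write_text(json.dumps(sidecar, indent=1))
            row["trace_path"] = str(path)
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "manifest.csv", index=False)
    return traces, manifest


# ---------------------------------------------------------------------------
# synthetic genomes

_RR_FIRST40 = re.compile(r"RR")
_CXXCH = re.compile(r"C..CH")


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _scrub(seq: str, scrub_tat_window: bool = True, scrub_cxxch: bool = True) -> str:
    """Remove accidental diagnostic motifs from a random sequence so that
    planted truth is the only signal the scanner can find."""
    s = list(seq)
    if scrub_tat_window:
        # no RR pairs anywhere near the N-terminus -> no TAT consensus
        for m in _RR_FIRST40.finditer("".join(s[:45])):
            s[m.start() + 1] = "K"
    if scrub_cxxch:
        while True:
            m = _CXXCH.search("".join(s))
            if m is None:
                break
            s[m.start()] = "S"
    return "".join(s)


def _mono_cytc(rng: random.Random) -> str:
    body = _scrub(_random_protein(rng, 95))
    return SEC_SIGNAL + body[:40] + "CAGCH" + body[45:]


def _c4_cytc(rng: random.Random) -> str:
    body = _scrub(_random_protein(rng, 160))
    return SEC_SIGNAL + body[:50] + "CAGCH" + body[55:110] + "CMTCH" + body[115:]


def _fao_protein(rng: random.Random, tat: bool, fused: bool = False) -> str:
    core = _scrub(_random_protein(rng, 470))
    prefix = TAT_SIGNAL if tat else "M" + _scrub(_random_protein(rng, 18))
    if fused:
        tail = _scrub(_random_protein(rng, 90))
        return prefix + core + tail[:40] + "CAGCH" + tail[45:]
    return prefix + core


def _decoy(rng: random.Random) -> str:
    return "M" + _scrub(_random_protein(rng, rng.randint(150, 300)))


@dataclass
class _ContigBuilder:
    contig_id: str
    gap_range: tuple[int, int]
    rng: random.Random
    pos: int = 1
    genes: list[GeneRecord] = field(default_factory=list)
    n: int = 0

    def add(self, protein: str, product: str, locus: str | None = None) -> GeneRecord:
        locus = locus or f"{self.contig_id}_g{self.n:03d}"
        length_nt = 3 * (len(protein) + 1)
        start = self.pos + self.rng.randint(*self.gap_range)
        rec = GeneRecord(locus_id=locus, contig_id=self.contig_id, start=start,
                         end=start + length_nt - 1, strand="+",
                         product=product, protein=protein)
        self.pos = rec.end
        self.genes.append(rec)
        self.n += 1
        return rec


def gen_synthetic_operons(
    layout: dict[str, int] | None = None,
    config: SynthConfig | None = None,
    out_path: str | Path | None = None,
):
    """Plant FAO operons of the requested categories into synthetic contigs.

    ``layout`` maps category -> number of planted FAO genes (default one of
    each).  Each planted FAO sits on its own contig with decoy genes around
    it; the blue configuration plants an adjacent monoheme CytC gene in the
    exemplar nicA2-like(TAT) - cytC - pnao-like(TAT) operon arrangement, so
    a blue layout entry contributes two FAO loci.  Returns
    ``(contigs, truth)`` where contigs is {contig_id: [GeneRecord]} and
    truth a DataFrame of intended categories; with ``out_path`` the records
    are also written as a GenBank flat file.
    """
    import pandas as pd

    config = config or SynthConfig()
    layout = layout if layout is not None else {c: 1 for c in
                                                ("black", "blue", "green", "red")}
    bad = set(layout) - {"black", "blue", "green", "red"}
    if bad:
        raise ValueError(f"unknown categories in layout: {sorted(bad)}")
    rng = random.Random(config.seed)

    contigs: dict[str, list[GeneRecord]] = {}
    truth_rows = []
    ci = 0
    for category in ("black", "blue", "green", "red"):
        for _ in range(layout.get(category, 0)):
            cb = _ContigBuilder(f"synthctg{ci:03d}", config.intergenic_gap, rng)
            ci += 1
            for _ in range(config.decoys_per_contig):
                cb.add(_decoy(rng), "hypothetical protein")
            if category == "black":
                fao = cb.add(_fao_protein(rng, tat=False),
                             "flavin amine oxidoreductase")
                truth_rows.append((fao.locus_id, cb.contig_id, "black"))
            elif category == "blue":
                fao1 = cb.add(_fao_protein(rng, tat=True),
                              "flavin amine oxidoreductase (nicA2-like)")
                cb.add(_mono_cytc(rng), "cytochrome c")
                fao2 = cb.add(_fao_protein(rng, tat=True),
                              "flavin amine oxidoreductase (pnao-like)")
                truth_rows.append((fao1.locus_id, cb.contig_id, "blue"))
                truth_rows.append((fao2.locus_id, cb.contig_id, "blue"))
            elif category == "green":
                fao = cb.add(_fao_protein(rng, tat=True, fused=True),
                             "flavin amine oxidoreductase-cytochrome c fusion")
                truth_rows.append((fao.locus_id, cb.contig_id, "green"))
            else:  # red
                fao = cb.add(_fao_protein(rng, tat=True),
                             "flavin amine oxidoreductase")
                truth_rows.append((fao.locus_id, cb.contig_id, "red"))
            for _ in range(config.decoys_per_contig):
                cb.add(_decoy(rng), "hypothetical protein")
            contigs[cb.contig_id] = cb.genes

    truth = pd.DataFrame(truth_rows, columns=["locus", "contig", "category"])
    if out_path is not None:
        write_genbank(contigs, out_path, rng_seed=config.seed)
    return contigs, truth


def write_genbank(contigs: dict[str, list[GeneRecord]], path: str | Path,
                  rng_seed: int = 0) -> None:
    """Serialize synthetic contigs as a GenBank flat file (CDS features carry
    the protein in /translation; the nucleotide sequence is random filler of
    the correct length)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rng = random.Random(rng_seed ^ 0x5EED)
    records = []
    for contig_id, genes in contigs.items():
        length = (max(g.end for g in genes) + 100) if genes else 100
        seq = Seq("".join(rng.choice("ACGT") for _ in range(length)))
        rec = SeqRecord(seq, id=contig_id, name=contig_id[:16],
                        description="synthetic contig with planted FAO operons")
        rec.annotations["molecule_type"] = "DNA"
        for g in genes:
            feat = SeqFeature(
                FeatureLocation(g.start - 1, g.end,
                                strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [g.locus_id], "product": [g.product],
                            "translation": [g.protein]},
            )
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# character-mapped trees

def gen_character_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    alpha: float = 0.5,
    seed: int = 0,
    states: tuple[str, ...] = ("black", "blue", "green", "red"),
):
    """Yule tree with a k-state equal-rates character evolved along it.

    The root state is uniform; along every branch, state changes arrive with
    exponential waiting times at total rate ``alpha`` and jump to a uniform
    choice among the other states.  Returns ``(tree, tip_states,
    node_states, events)`` where events is a list of (edge child label,
    from_state, to_state) true change events and node_states the true state
    at every (labelled) node.
    """
    import dendropy
    from dendropy.simulate import treesim

    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    tree.is_rooted = True
    # the simulation stops at the n-th speciation, leaving the last cherry
    # with zero-length tip edges; extend every extant tip by the waiting
    # time to the next (unrealized) event so the tree stays ultrametric
    # with strictly positive terminal branches
    extra = rng.expovariate(birth_rate * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    from .ancestral_mk import label_internal_nodes, _node_key  # deterministic labels

    label_internal_nodes(tree)
    k = len(states)
    node_states: dict[str, str] = {}
    events: list[tuple[str, str, str]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = states[rng.randrange(k)]
        else:
            state = node_states[_node_key(node.parent_node)]
            remaining = node.edge.length or 0.0
            if alpha > 0:
                wait = rng.expovariate(alpha)
                while wait < remaining:
                    others = [s for s in states if s != state]
                    new = others[rng.randrange(k - 1)]
                    events.append((_node_key(node), state, new))
                    state = new
                    remaining -= wait
                    wait = rng.expovariate(alpha)
        node_states[_node_key(node)] = state
    tip_states = {_node_key(leaf): node_states[_node_key(leaf)]
                  for leaf in tree.leaf_node_iter()}
    return tree, tip_states, node_states, events
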
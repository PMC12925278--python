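"""Generate the synthetic fractionated LFQ experiment used by the later steps.

Emulates the EV study design — Control vs inflammasome-activated (LN), three
biological replicates each, 2 vs 4 gel fractions, 2-3 technical injections —
with 10 % of proteins spiked at |log2FC| = 2 and intensity-dependent (MNAR)
plus random (MCAR) dropout. Writes runs.tsv, design.tsv, ids.tsv, truth.tsv
under results/sim/.
"""

from pathlib import Path

from infosome_lfq.io import write_id_table
from infosome_lfq.simulate import SimulationConfig, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    sim = simulate(cfg)
    sim.matrix.to_tsv(OUT / "runs.tsv")
    sim.design.to_tsv(OUT / "design.tsv")
    write_id_table(sim.id_records, OUT / "ids.tsv")
    sim.truth.proteins.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    n_missing = sim.matrix.n_missing
    n_cells = sim.matrix.data.size
    print(f"simulated {cfg.n_proteins} proteins x {len(sim.design.run_ids)} runs "
          f"(seed {SEED})")
    print(f"  spiked proteins: {int(sim.truth.proteins['spiked'].sum())} "
          f"at |log2FC| = {cfg.spike_log2fc}")
    print(f"  missing cells: {n_missing}/{n_cells} ({n_missing / n_cells:.1%})")
    print(f"  wrote {OUT}/runs.tsv, design.tsv, ids.tsv, truth.tsv")


if __name__ == "__main__":
    main()
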
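"""Generate the synthetic study slides and their ground truth.

Writes two datasets under results/:
* a single-component two-zone slide (tumor-core disc + periphery annulus
  planted at the published region composition vectors, ~21k cells), and
* a two-component case (intraductal + invasive, the invasive component
  with a proportionally smaller core and a CD4-down/CD8-up shift).
"""

from pathlib import Path

from iopn_tme.cell_io import write_cells
from iopn_tme.pipeline import simulate_two_component_case, simulate_two_zone_case

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    cells, truth, spec = simulate_two_zone_case(seed=SEED)
    write_cells(cells, OUT / "slide_two_zone.csv")
    truth.to_json(OUT / "slide_two_zone_truth.json")
    spec.to_yaml(OUT / "slide_two_zone_spec.yaml")
    print(f"two-zone slide: {len(cells)} cells "
          f"({(cells.zone_truth == 'core').sum()} core, "
          f"{(cells.zone_truth == 'periphery').sum()} periphery)")

    cells2, spec2 = simulate_two_component_case(seed=SEED)
    write_cells(cells2, OUT / "slide_two_component.csv")
    spec2.to_yaml(OUT / "slide_two_component_spec.yaml")
    print(f"two-component case: {len(cells2)} cells "
          f"({(cells2.component == 'invasive').sum()} invasive)")
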
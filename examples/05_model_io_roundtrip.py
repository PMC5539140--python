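"""Model serialization: json-v1 and SBML Level 3 + FBC round trips.

Writes a randomized TAG fixture in both dialects, reads each back, and
confirms model equality — including flux bounds, the objective, and gene
associations.  The candidate table writer produces the tab-separated
ranked-knockout listing (reaction ids, objectives, mapped genes).
"""

import tempfile
from pathlib import Path

from tagknock import (
    OptKnockConfig,
    enumerate_candidates,
    make_tag_toy,
    read_model,
    write_candidate_table,
    write_model,
)

model, _ = make_tag_toy(n_extra_branches=3, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for dialect, suffix in (("json-v1", ".json"), ("sbml3-fbc", ".xml")):
        path = tmp / f"model{suffix}"
        write_model(model, path, dialect=dialect)
        back = read_model(path)
        print(f"{dialect}: round-trip equality = {back.model == model}")

    config = OptKnockConfig(
        target_reaction_id="DM_tag", biomass_reaction_id="BIO", max_deletions=1, n_candidates=5
    )
    table = tmp / "candidates.tsv"
    write_candidate_table(enumerate_candidates(model, config), model, table)
    print("\nranked candidate table:")
    print(table.read_text())
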
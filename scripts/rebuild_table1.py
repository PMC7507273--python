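"""Optional driver: evaluate all four models on a locally available corpus.

This script is for users who have downloaded one of the public gold
standards (e.g. the BC5CDR PubTator files together with the MEDIC or
CTD-Chemicals vocabulary, or a PubTator export of CRAFT with a ChEBI
OBO release) — none of which ship with this repository.  It runs
string_matching, ppr_ic, reel_corpus and reel_kb_corpus over the corpus
and prints the micro-averaged P/R/F1 table.

Example:
    python scripts/rebuild_table1.py \
        --corpus CDR_TestSet.PubTator.txt --kb CTD_chemicals.tsv \
        --kb-format ctd --entity-type Chemical --use-gold-cid \
        --expand-shared --seed 7
"""

from __future__ import annotations

import argparse

from reel.corpus import read_gold_relations, read_pubtator, read_re_output
from reel.graph import expand_shared_entity_relations
from reel.kb import compute_ic, load_ctd_chemicals_tsv, load_obo, read_frequency_tsv
from reel.metrics import evaluation_table, evaluate
from reel.ppr import MODELS, PPRConfig, run_model


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--corpus", required=True, help="PubTator-format corpus")
    parser.add_argument("--kb", required=True, help="OBO file or CTD chemicals TSV")
    parser.add_argument("--kb-format", choices=["obo", "ctd"], default="obo")
    parser.add_argument("--prefix", default=None, help="CURIE prefix filter for OBO")
    parser.add_argument("--entity-type", default=None,
                        help="keep only mentions of this type (Chemical/Disease)")
    parser.add_argument("--use-gold-cid", action="store_true",
                        help="use the corpus CID lines as the relation source")
    parser.add_argument("--re-output", default=None,
                        help="relation-extraction output TSV (effect/noeffect)")
    parser.add_argument("--expand-shared", action="store_true",
                        help="derive shared-chemical/shared-disease pairs")
    parser.add_argument("--ic-freq", default=None, help="concept frequency TSV")
    parser.add_argument("--top-k", type=int, default=10)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--models", nargs="+", default=list(MODELS), choices=MODELS)
    args = parser.parse_args()

    if args.kb_format == "ctd":
        kb = load_ctd_chemicals_tsv(args.kb)
    else:
        kb = load_obo(args.kb, prefix_filter=args.prefix)

    documents = read_pubtator(args.corpus)
    if args.entity_type:
        for doc in documents:
            doc.mentions = [m for m in doc.mentions if m.entity_type == args.entity_type]

    relations = None
    if args.use_gold_cid:
        relations = read_gold_relations(args.corpus)
        if args.expand_shared:
            relations = expand_shared_entity_relations(relations)
    if args.re_output:
        re_rels = read_re_output(args.re_output)
        relations = re_rels if relations is None else relations | re_rels

    ic = compute_ic(kb, read_frequency_tsv(args.ic_freq) if args.ic_freq else None)

    table = {}
    for model in args.models:
        results = run_model(documents, kb, relations, ic, model,
                            PPRConfig(seed=args.seed), top_k=args.top_k)
        table[model] = evaluate(results, documents)
    print(evaluation_table(table))


if __name__ == "__main__":
    main()
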
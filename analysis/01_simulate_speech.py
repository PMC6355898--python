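"""Generate the synthetic speech study: a topic corpus for the semantic
space, drifting responses from a group of simulated speakers, and
lexical norms.

Writes results/corpus.txt, results/transcripts.tsv,
results/true_drift.tsv and results/norms.tsv.
"""

import argparse
from pathlib import Path

from cohera.io import write_transcripts
from cohera.synthetic import (
    DriftSpec,
    TopicModelSpec,
    generate_corpus,
    generate_norms,
    generate_responses,
)

N_PARTICIPANTS = 8
N_DOCS = 64


def main(seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    topic_spec = TopicModelSpec()
    corpus, labels = generate_corpus(topic_spec, n_docs=N_DOCS, seed=seed)
    with open(out / "corpus.txt", "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc) + "\n")

    responses, truth = generate_responses(
        0, DriftSpec(), N_PARTICIPANTS, seed=seed + 1, topic_spec=topic_spec
    )
    write_transcripts(responses, out / "transcripts.tsv")
    truth.to_csv(out / "true_drift.tsv", sep="\t", index=False)

    vocab = sorted({t for r in responses for t in r.tokens})
    norms = generate_norms(vocab, seed=seed + 2)
    norms.norms.assign(
        is_noun=[w in norms.noun_list for w in norms.norms.index],
        is_closed_class=[w in norms.closed_class_list
                         for w in norms.norms.index],
    ).to_csv(out / "norms.tsv", sep="\t", index_label="word")

    n_words = sum(len(r.tokens) for r in responses)
    print(f"corpus: {N_DOCS} documents, {topic_spec.n_topics} topics")
    print(f"responses: {N_PARTICIPANTS} speakers, {n_words} words total")
    print(f"mean true on-topic proportion by block:")
    print(truth.groupby("block_index")["true_on_topic"].mean().round(2)
          .to_string())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out)
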
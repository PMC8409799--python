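#!/usr/bin/env bash
# The same round trip as 04, but through the command-line roles, exchanging
# only files: the server step sees the public key, the model, and the
# encrypted query — never a genotype.
set -euo pipefail
WD=$(mktemp -d)
trap 'rm -rf "$WD"' EXIT

cryptimpute keygen --key-bits 1024 --seed 7 \
    --out-public "$WD/public.json" --out-private "$WD/private.json"

cryptimpute simulate --n-individuals 300 --seed 7 \
    --out-vcf "$WD/panel.vcf" --out-manifest "$WD/manifest.tsv"

cryptimpute train --panel "$WD/panel.vcf" --key-bits 1024 \
    --out-model "$WD/model.json"

# client side -------------------------------------------------------------
cryptimpute encrypt --panel "$WD/panel.vcf" --model "$WD/model.json" \
    --public-key "$WD/public.json" --out-query "$WD/query.json"

# server side (blind) -----------------------------------------------------
cryptimpute impute --query "$WD/query.json" --model "$WD/model.json" \
    --public-key "$WD/public.json" --threads 2 --out-result "$WD/result.json"

# client side -------------------------------------------------------------
cryptimpute decrypt --result "$WD/result.json" --model "$WD/model.json" \
    --public-key "$WD/public.json" --private-key "$WD/private.json" \
    --out-tsv "$WD/predictions.tsv"

cryptimpute evaluate --predictions "$WD/predictions.tsv" \
    --truth "$WD/panel.vcf" --out-report "$WD/report.json"

echo "--- report ---"
cat "$WD/report.json" | python -c "import json,sys; d=json.load(sys.stdin); \
print('accuracy:', round(d['accuracy'],4), ' micro-AUC:', round(d['micro_auc'],4))"
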
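"""Cluster-validity indices as a proxy for embedding quality.

A feature extractor is useful for coreset selection when items of the
same class sit close together and classes sit apart. Davies-Bouldin
(0 is best) and Silhouette (1 is best) quantify that, here on the same
cloud at two separation settings standing in for a strong and a weak
extractor.
"""

import coreselect as cs

for separation, tag in [(8.0, "strong extractor (well-separated classes)"),
                        (1.5, "weak extractor   (overlapping classes)")]:
    spec = cs.BlobSpec(
        n_classes=10, class_counts=[80] * 10, dim=16, separation=separation, seed=0
    )
    embeddings, labels = cs.generate_blobs(spec)
    db = cs.davies_bouldin(embeddings, labels)
    sil = cs.silhouette(embeddings, labels)
    print(f"{tag}: Davies-Bouldin {db:6.3f}   Silhouette {sil:6.3f}")
print("-> lower Davies-Bouldin / higher Silhouette on true labels predicts")
print("   that K-means clusters will align with classes, hence better coresets")
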
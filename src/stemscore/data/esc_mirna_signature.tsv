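hsa-miR-141	up
hsa-miR-148a	up
hsa-miR-187	up
hsa-miR-18a	up
hsa-miR-18b	up
hsa-miR-20a	up
hsa-miR-20b	up
hsa-miR-200c	up
hsa-miR-19a	up
hsa-miR-19b	up
hsa-miR-302a	up
hsa-miR-302astar	up
hsa-miR-302b	up
hsa-miR-302bstar	up
hsa-miR-302c	up
hsa-miR-302d	up
hsa-miR-367	up
hsa-miR-363	up
hsa-miR-363star	up
hsa-miR-372	up
hsa-miR-498	up
hsa-miR-512-3p	up
hsa-miR-515-5p	up
hsa-miR-517a	up
hsa-miR-517b	up
hsa-miR-518b	up
hsa-miR-518c	up
hsa-miR-520f	up
hsa-miR-520g	up
hsa-miR-520h	up
hsa-miR-524star	up
hsa-miR-92b	up
hsa-miR-96	up
hsa-let-7a	down
hsa-let-7e	down
hsa-let-7f	down
hsa-let-7g	down
hsa-miR-100	down
hsa-miR-125a	down
hsa-miR-125b	down
hsa-miR-132	down
hsa-miR-137	down
hsa-miR-143	down
hsa-miR-145	down
hsa-miR-152	down
hsa-miR-181a	down
hsa-miR-181b	down
hsa-miR-21	down
hsa-miR-22	down
hsa-miR-222	down
hsa-miR-23a	down
hsa-miR-23b	down
hsa-miR-24	down
hsa-miR-27a	down
hsa-miR-27b	down
hsa-miR-28	down
hsa-miR-29a	down
hsa-miR-376a	down
hsa-miR-495	down
hsa-miR-99a	down
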
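wavelength_nm,leaf_green
300,0.03
301,0.03
302,0.03
303,0.03
304,0.03
305,0.03
306,0.03
307,0.03
308,0.03
309,0.03
310,0.03
311,0.03
312,0.03
313,0.03
314,0.03
315,0.03
316,0.03
317,0.03
318,0.03
319,0.03
320,0.03
321,0.03
322,0.03
323,0.03
324,0.03
325,0.03
326,0.03
327,0.03
328,0.03
329,0.03
330,0.03
331,0.03
332,0.03
333,0.03
334,0.03
335,0.03
336,0.03
337,0.03
338,0.03
339,0.03
340,0.03
341,0.03
342,0.03
343,0.03
344,0.03
345,0.03
346,0.03
347,0.03
348,0.03
349,0.03
350,0.03
351,0.03
352,0.03
353,0.03
354,0.03
355,0.03
356,0.03
357,0.03
358,0.03
359,0.03
360,0.03
361,0.03
362,0.03
363,0.03
364,0.03
365,0.03
366,0.03
367,0.03
368,0.03
369,0.03
370,0.03
371,0.03
372,0.03
373,0.03
374,0.03
375,0.030000001
376,0.030000001
377,0.030000001
378,0.030000001
379,0.030000001
380,0.030000002
381,0.030000002
382,0.030000003
383,0.030000003
384,0.030000004
385,0.030000005
386,0.030000006
387,0.030000007
388,0.030000009
389,0.030000011
390,0.030000014
391,0.030000016
392,0.03000002
393,0.030000024
394,0.03000003
395,0.030000036
396,0.030000044
397,0.030000053
398,0.030000064
399,0.030000078
400,0.030000094
401,0.030000113
402,0.030000136
403,0.030000164
404,0.030000196
405,0.030000236
406,0.030000282
407,0.030000338
408,0.030000404
409,0.030000482
410,0.030000574
411,0.030000684
412,0.030000813
413,0.030000965
414,0.030001145
415,0.030001356
416,0.030001604
417,0.030001896
418,0.030002237
419,0.030002637
420,0.030003104
421,0.03000365
422,0.030004286
423,0.030005026
424,0.030005887
425,0.030006887
426,0.030008047
427,0.03000939
428,0.030010944
429,0.030012738
430,0.030014809
431,0.030017195
432,0.03001994
433,0.030023095
434,0.030026716
435,0.030030865
436,0.030035614
437,0.030041043
438,0.03004724
439,0.030054305
440,0.030062349
441,0.030071495
442,0.030081879
443,0.030093655
444,0.030106991
445,0.030122073
446,0.030139108
447,0.030158321
448,0.030179962
449,0.030204307
450,0.030231654
451,0.030262335
452,0.030296708
453,0.030335165
454,0.030378133
455,0.030426078
456,0.030479501
457,0.03053895
458,0.030605011
459,0.030678322
460,0.030759566
461,0.030849478
462,0.030948846
463,0.031058515
464,0.031179383
465,0.031312412
466,0.031458621
467,0.031619094
468,0.031794976
469,0.031987478
470,0.032197877
471,0.032427512
472,0.03267779
473,0.032950182
474,0.033246222
475,0.033567506
476,0.033915691
477,0.034292489
478,0.034699667
479,0.035139042
480,0.035612475
481,0.036121865
482,0.036669146
483,0.037256276
484,0.037885233
485,0.038558002
486,0.039276569
487,0.040042908
488,0.040858973
489,0.041726682
490,0.042647907
491,0.04362446
492,0.04465808
493,0.045750415
494,0.046903011
495,0.04811729
496,0.049394543
497,0.050735905
498,0.052142343
499,0.053614637
500,0.055153366
501,0.05675889
502,0.058431331
503,0.060170564
504,0.061976196
505,0.063847554
506,0.065783674
507,0.067783282
508,0.069844793
509,0.071966293
510,0.074145533
511,0.076379926
512,0.078666541
513,0.081002097
514,0.083382968
515,0.085805183
516,0.088264427
517,0.090756055
518,0.093275091
519,0.095816248
520,0.098373939
521,0.10094229
522,0.10351517
523,0.10608619
524,0.10864875
525,0.11119606
526,0.11372116
527,0.11621695
528,0.11867622
529,0.1210917
530,0.12345609
531,0.12576208
532,0.12800238
533,0.1301698
534,0.13225725
535,0.13425781
536,0.13616471
537,0.13797144
538,0.13967174
539,0.14125966
540,0.14272957
541,0.14407621
542,0.14529473
543,0.1463807
544,0.14733015
545,0.14813957
546,0.14880598
547,0.14932689
548,0.14970037
549,0.14992502
550,0.15
551,0.14992502
552,0.14970037
553,0.14932689
554,0.14880598
555,0.14813957
556,0.14733015
557,0.1463807
558,0.14529473
559,0.14407621
560,0.14272957
561,0.14125966
562,0.13967174
563,0.13797144
564,0.13616471
565,0.13425781
566,0.13225725
567,0.1301698
568,0.12800238
569,0.12576208
570,0.12345609
571,0.1210917
572,0.11867622
573,0.11621695
574,0.11372116
575,0.11119606
576,0.10864875
577,0.10608619
578,0.10351517
579,0.10094229
580,0.098373939
581,0.095816249
582,0.093275091
583,0.090756055
584,0.088264428
585,0.085805183
586,0.083382969
587,0.081002098
588,0.078666542
589,0.076379928
590,0.074145535
591,0.071966295
592,0.069844796
593,0.067783285
594,0.065783677
595,0.063847558
596,0.061976201
597,0.06017057
598,0.058431338
599,0.056758898
600,0.055153376
601,0.053614649
602,0.052142356
603,0.050735921
604,0.049394562
605,0.048117312
606,0.046903036
607,0.045750446
608,0.044658116
609,0.043624503
610,0.042647957
611,0.041726741
612,0.040859043
613,0.040042991
614,0.039276667
615,0.038558118
616,0.03788537
617,0.037256438
618,0.036669337
619,0.036122091
620,0.035612742
621,0.035139358
622,0.03470004
623,0.034292929
624,0.033916211
625,0.03356812
626,0.033246947
627,0.032951039
628,0.032678803
629,0.032428708
630,0.03219929
631,0.031989149
632,0.031796949
633,0.031621425
634,0.031461375
635,0.031315665
636,0.031183226
637,0.031063055
638,0.03095421
639,0.030855814
640,0.03076705
641,0.030687164
642,0.030615457
643,0.030551289
644,0.030494079
645,0.030443298
646,0.030398476
647,0.030359196
648,0.030325096
649,0.03029587
650,0.030271269
651,0.030251102
652,0.03023524
653,0.030223617
654,0.030216237
655,0.030213178
656,0.030214601
657,0.030220757
658,0.030231998
659,0.03024879
660,0.030271731
661,0.030301568
662,0.030339215
663,0.030385788
664,0.030442628
665,0.03051134
666,0.030593836
667,0.03069238
668,0.030809649
669,0.030948791
670,0.031113503
671,0.031308111
672,0.031537659
673,0.031808011
674,0.032125958
675,0.03249933
676,0.03293711
677,0.033449546
678,0.034048242
679,0.034746237
680,0.03555803
681,0.036499554
682,0.037588055
683,0.038841863
684,0.040280007
685,0.041921648
686,0.043785311
687,0.045887876
688,0.048243365
689,0.050861536
690,0.053746377
691,0.056894624
692,0.060294475
693,0.063924701
694,0.067754349
695,0.071743215
696,0.075843148
697,0.080000164
698,0.084157184
699,0.088257134
700,0.092246027
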
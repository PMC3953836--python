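wavelength_nm,irradiance_6500K
300,0.38759006
301,0.39196218
302,0.39633689
303,0.40071369
304,0.40509213
305,0.40947172
306,0.413852
307,0.4182325
308,0.42261277
309,0.42699234
310,0.43137078
311,0.43574762
312,0.44012243
313,0.44449477
314,0.4488642
315,0.45323031
316,0.45759266
317,0.46195084
318,0.46630444
319,0.47065303
320,0.47499623
321,0.47933362
322,0.48366482
323,0.48798943
324,0.49230708
325,0.49661738
326,0.50091995
327,0.50521444
328,0.50950047
329,0.51377768
330,0.51804572
331,0.52230425
332,0.52655291
333,0.53079137
334,0.5350193
335,0.53923636
336,0.54344224
337,0.54763661
338,0.55181917
339,0.5559896
340,0.5601476
341,0.56429288
342,0.56842514
343,0.57254409
344,0.57664946
345,0.58074096
346,0.58481832
347,0.58888128
348,0.59292957
349,0.59696294
350,0.60098112
351,0.60498389
352,0.60897098
353,0.61294218
354,0.61689723
355,0.62083592
356,0.62475802
357,0.62866332
358,0.63255159
359,0.63642264
360,0.64027625
361,0.64411223
362,0.64793038
363,0.65173052
364,0.65551245
365,0.659276
366,0.66302098
367,0.66674723
368,0.67045458
369,0.67414287
370,0.67781193
371,0.68146161
372,0.68509176
373,0.68870224
374,0.6922929
375,0.6958636
376,0.69941421
377,0.70294461
378,0.70645465
379,0.70994423
380,0.71341322
381,0.71686152
382,0.720289
383,0.72369557
384,0.72708112
385,0.73044555
386,0.73378877
387,0.73711068
388,0.7404112
389,0.74369025
390,0.74694774
391,0.75018359
392,0.75339773
393,0.7565901
394,0.75976062
395,0.76290923
396,0.76603586
397,0.76914047
398,0.772223
399,0.77528339
400,0.7783216
401,0.78133758
402,0.7843313
403,0.7873027
404,0.79025177
405,0.79317845
406,0.79608273
407,0.79896457
408,0.80182396
409,0.80466086
410,0.80747526
411,0.81026714
412,0.81303649
413,0.8157833
414,0.81850756
415,0.82120925
416,0.82388838
417,0.82654495
418,0.82917895
419,0.8317904
420,0.83437928
421,0.83694562
422,0.83948941
423,0.84201068
424,0.84450944
425,0.8469857
426,0.84943948
427,0.8518708
428,0.85427969
429,0.85666616
430,0.85903024
431,0.86137197
432,0.86369137
433,0.86598847
434,0.86826331
435,0.87051592
436,0.87274633
437,0.8749546
438,0.87714075
439,0.87930483
440,0.88144688
441,0.88356694
442,0.88566507
443,0.88774132
444,0.88979572
445,0.89182833
446,0.89383921
447,0.89582841
448,0.89779597
449,0.89974197
450,0.90166645
451,0.90356947
452,0.9054511
453,0.9073114
454,0.90915042
455,0.91096824
456,0.91276491
457,0.9145405
458,0.91629509
459,0.91802873
460,0.91974149
461,0.92143345
462,0.92310467
463,0.92475523
464,0.9263852
465,0.92799466
466,0.92958367
467,0.93115232
468,0.93270067
469,0.93422881
470,0.93573682
471,0.93722476
472,0.93869273
473,0.94014079
474,0.94156904
475,0.94297755
476,0.9443664
477,0.94573568
478,0.94708546
479,0.94841584
480,0.9497269
481,0.95101871
482,0.95229138
483,0.95354497
484,0.95477958
485,0.9559953
486,0.95719221
487,0.9583704
488,0.95952996
489,0.96067097
490,0.96179353
491,0.96289772
492,0.96398363
493,0.96505136
494,0.96610099
495,0.96713261
496,0.96814632
497,0.9691422
498,0.97012035
499,0.97108085
500,0.97202381
501,0.9729493
502,0.97385743
503,0.97474829
504,0.97562197
505,0.97647855
506,0.97731814
507,0.97814083
508,0.9789467
509,0.97973586
510,0.9805084
511,0.98126441
512,0.98200397
513,0.9827272
514,0.98343418
515,0.984125
516,0.98479976
517,0.98545855
518,0.98610146
519,0.9867286
520,0.98734004
521,0.9879359
522,0.98851625
523,0.98908119
524,0.98963083
525,0.99016524
526,0.99068453
527,0.99118879
528,0.99167811
529,0.99215258
530,0.9926123
531,0.99305736
532,0.99348785
533,0.99390387
534,0.99430551
535,0.99469285
536,0.99506601
537,0.99542506
538,0.99577009
539,0.99610121
540,0.9964185
541,0.99672205
542,0.99701196
543,0.99728831
544,0.99755121
545,0.99780073
546,0.99803696
547,0.99826001
548,0.99846996
549,0.99866689
550,0.99885091
551,0.99902209
552,0.99918054
553,0.99932633
554,0.99945955
555,0.9995803
556,0.99968866
557,0.99978473
558,0.99986858
559,0.99994031
560,1
561,1.0000477
562,1.0000836
563,1.0001077
564,1.0001201
565,1.0001209
566,1.0001102
567,1.0000881
568,1.0000546
569,1.0000098
570,0.99995391
571,0.99988688
572,0.99980884
573,0.99971987
574,0.99962005
575,0.99950947
576,0.99938821
577,0.99925635
578,0.99911398
579,0.99896117
580,0.99879801
581,0.99862458
582,0.99844095
583,0.99824722
584,0.99804345
585,0.99782972
586,0.99760613
587,0.99737274
588,0.99712963
589,0.99687688
590,0.99661458
591,0.99634279
592,0.99606159
593,0.99577107
594,0.99547129
595,0.99516234
596,0.99484428
597,0.9945172
598,0.99418117
599,0.99383626
600,0.99348254
601,0.9931201
602,0.99274901
603,0.99236933
604,0.99198114
605,0.99158452
606,0.99117953
607,0.99076625
608,0.99034475
609,0.98991509
610,0.98947736
611,0.98903161
612,0.98857793
613,0.98811637
614,0.98764701
615,0.98716992
616,0.98668517
617,0.98619282
618,0.98569294
619,0.9851856
620,0.98467086
621,0.9841488
622,0.98361947
623,0.98308295
624,0.9825393
625,0.98198858
626,0.98143086
627,0.98086621
628,0.98029468
629,0.97971635
630,0.97913127
631,0.97853951
632,0.97794113
633,0.97733619
634,0.97672475
635,0.97610688
636,0.97548264
637,0.97485209
638,0.97421528
639,0.97357228
640,0.97292315
641,0.97226795
642,0.97160673
643,0.97093956
644,0.97026649
645,0.96958759
646,0.9689029
647,0.96821249
648,0.96751641
649,0.96681472
650,0.96610747
651,0.96539473
652,0.96467655
653,0.96395297
654,0.96322407
655,0.96248988
656,0.96175047
657,0.96100589
658,0.9602562
659,0.95950143
660,0.95874166
661,0.95797693
662,0.95720729
663,0.9564328
664,0.9556535
665,0.95486945
666,0.9540807
667,0.9532873
668,0.9524893
669,0.95168674
670,0.95087968
671,0.95006817
672,0.94925226
673,0.94843199
674,0.94760741
675,0.94677858
676,0.94594553
677,0.94510832
678,0.94426699
679,0.94342158
680,0.94257216
681,0.94171875
682,0.94086141
683,0.94000018
684,0.93913511
685,0.93826624
686,0.93739362
687,0.93651729
688,0.93563729
689,0.93475367
690,0.93386647
691,0.93297573
692,0.9320815
693,0.93118381
694,0.93028272
695,0.92937826
696,0.92847047
697,0.9275594
698,0.92664508
699,0.92572756
700,0.92480688
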
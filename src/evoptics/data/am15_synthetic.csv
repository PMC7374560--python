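# Synthetic AM1.5-style global solar spectral irradiance.
# Smooth 5778 K Planck spectrum scaled to a realistic peak level;
# a stand-in for the ASTM G-173 global-tilt table (same dialect).
wavelength_nm,irradiance_W_m2_nm
300,0.738848
301,0.746978
302,0.755102
303,0.763218
304,0.771325
305,0.779422
306,0.787509
307,0.795584
308,0.803646
309,0.811694
310,0.819727
311,0.827745
312,0.835746
313,0.84373
314,0.851695
315,0.859641
316,0.867567
317,0.875472
318,0.883354
319,0.891214
320,0.89905
321,0.906862
322,0.914648
323,0.922408
324,0.930141
325,0.937847
326,0.945524
327,0.953172
328,0.960791
329,0.968378
330,0.975935
331,0.983459
332,0.990951
333,0.998409
334,1.00583
335,1.01322
336,1.02058
337,1.0279
338,1.03518
339,1.04243
340,1.04963
341,1.0568
342,1.06393
343,1.07103
344,1.07808
345,1.08509
346,1.09206
347,1.09899
348,1.10588
349,1.11273
350,1.11953
351,1.12629
352,1.13301
353,1.13968
354,1.14631
355,1.15289
356,1.15943
357,1.16593
358,1.17238
359,1.17878
360,1.18514
361,1.19145
362,1.19771
363,1.20393
364,1.21009
365,1.21621
366,1.22229
367,1.22831
368,1.23429
369,1.24021
370,1.24609
371,1.25192
372,1.2577
373,1.26343
374,1.26911
375,1.27474
376,1.28032
377,1.28585
378,1.29133
379,1.29676
380,1.30214
381,1.30747
382,1.31274
383,1.31797
384,1.32314
385,1.32827
386,1.33334
387,1.33836
388,1.34333
389,1.34825
390,1.35312
391,1.35794
392,1.3627
393,1.36742
394,1.37208
395,1.37669
396,1.38125
397,1.38576
398,1.39021
399,1.39462
400,1.39897
401,1.40328
402,1.40753
403,1.41173
404,1.41588
405,1.41997
406,1.42402
407,1.42802
408,1.43196
409,1.43586
410,1.4397
411,1.44349
412,1.44724
413,1.45093
414,1.45457
415,1.45816
416,1.4617
417,1.4652
418,1.46864
419,1.47203
420,1.47537
421,1.47867
422,1.48191
423,1.48511
424,1.48825
425,1.49135
426,1.4944
427,1.4974
428,1.50035
429,1.50326
430,1.50611
431,1.50892
432,1.51168
433,1.5144
434,1.51706
435,1.51968
436,1.52226
437,1.52478
438,1.52726
439,1.5297
440,1.53208
441,1.53442
442,1.53672
443,1.53897
444,1.54118
445,1.54334
446,1.54545
447,1.54753
448,1.54955
449,1.55154
450,1.55348
451,1.55537
452,1.55722
453,1.55903
454,1.5608
455,1.56252
456,1.56421
457,1.56585
458,1.56744
459,1.569
460,1.57051
461,1.57199
462,1.57342
463,1.57481
464,1.57616
465,1.57747
466,1.57874
467,1.57997
468,1.58116
469,1.58232
470,1.58343
471,1.5845
472,1.58554
473,1.58654
474,1.5875
475,1.58842
476,1.58931
477,1.59015
478,1.59096
479,1.59174
480,1.59248
481,1.59318
482,1.59384
483,1.59447
484,1.59507
485,1.59563
486,1.59615
487,1.59664
488,1.59709
489,1.59752
490,1.5979
491,1.59826
492,1.59858
493,1.59886
494,1.59912
495,1.59934
496,1.59953
497,1.59969
498,1.59981
499,1.59991
500,1.59997
501,1.6
502,1.6
503,1.59997
504,1.59991
505,1.59982
506,1.5997
507,1.59955
508,1.59937
509,1.59916
510,1.59892
511,1.59866
512,1.59837
513,1.59804
514,1.59769
515,1.59732
516,1.59691
517,1.59648
518,1.59602
519,1.59553
520,1.59502
521,1.59448
522,1.59392
523,1.59333
524,1.59272
525,1.59208
526,1.59141
527,1.59072
528,1.59001
529,1.58927
530,1.5885
531,1.58772
532,1.58691
533,1.58607
534,1.58522
535,1.58434
536,1.58343
537,1.58251
538,1.58156
539,1.58059
540,1.5796
541,1.57859
542,1.57756
543,1.5765
544,1.57543
545,1.57433
546,1.57321
547,1.57208
548,1.57092
549,1.56974
550,1.56854
551,1.56733
552,1.56609
553,1.56484
554,1.56356
555,1.56227
556,1.56096
557,1.55963
558,1.55829
559,1.55692
560,1.55554
561,1.55414
562,1.55272
563,1.55129
564,1.54984
565,1.54837
566,1.54689
567,1.54539
568,1.54387
569,1.54234
570,1.54079
571,1.53923
572,1.53765
573,1.53606
574,1.53445
575,1.53283
576,1.53119
577,1.52954
578,1.52787
579,1.52619
580,1.5245
581,1.52279
582,1.52107
583,1.51933
584,1.51758
585,1.51582
586,1.51405
587,1.51226
588,1.51046
589,1.50865
590,1.50683
591,1.50499
592,1.50314
593,1.50128
594,1.49941
595,1.49753
596,1.49563
597,1.49373
598,1.49181
599,1.48989
600,1.48795
601,1.486
602,1.48404
603,1.48207
604,1.4801
605,1.47811
606,1.47611
607,1.4741
608,1.47208
609,1.47006
610,1.46802
611,1.46598
612,1.46392
613,1.46186
614,1.45979
615,1.45771
616,1.45562
617,1.45352
618,1.45142
619,1.44931
620,1.44719
621,1.44506
622,1.44292
623,1.44078
624,1.43863
625,1.43647
626,1.43431
627,1.43214
628,1.42996
629,1.42777
630,1.42558
631,1.42338
632,1.42118
633,1.41897
634,1.41675
635,1.41453
636,1.4123
637,1.41006
638,1.40782
639,1.40558
640,1.40333
641,1.40107
642,1.39881
643,1.39654
644,1.39427
645,1.39199
646,1.38971
647,1.38742
648,1.38513
649,1.38283
650,1.38053
651,1.37823
652,1.37592
653,1.37361
654,1.37129
655,1.36897
656,1.36664
657,1.36431
658,1.36198
659,1.35964
660,1.35731
661,1.35496
662,1.35262
663,1.35027
664,1.34792
665,1.34556
666,1.3432
667,1.34084
668,1.33848
669,1.33611
670,1.33374
671,1.33137
672,1.32899
673,1.32662
674,1.32424
675,1.32186
676,1.31948
677,1.31709
678,1.3147
679,1.31231
680,1.30992
681,1.30753
682,1.30514
683,1.30274
684,1.30034
685,1.29794
686,1.29554
687,1.29314
688,1.29074
689,1.28834
690,1.28593
691,1.28353
692,1.28112
693,1.27871
694,1.2763
695,1.27389
696,1.27148
697,1.26907
698,1.26666
699,1.26425
700,1.26184
701,1.25942
702,1.25701
703,1.2546
704,1.25218
705,1.24977
706,1.24736
707,1.24494
708,1.24253
709,1.24012
710,1.2377
711,1.23529
712,1.23288
713,1.23046
714,1.22805
715,1.22564
716,1.22323
717,1.22082
718,1.21841
719,1.216
720,1.21359
721,1.21118
722,1.20877
723,1.20636
724,1.20396
725,1.20155
726,1.19915
727,1.19675
728,1.19434
729,1.19194
730,1.18954
731,1.18714
732,1.18475
733,1.18235
734,1.17995
735,1.17756
736,1.17517
737,1.17278
738,1.17039
739,1.168
740,1.16561
741,1.16323
742,1.16084
743,1.15846
744,1.15608
745,1.15371
746,1.15133
747,1.14895
748,1.14658
749,1.14421
750,1.14184
751,1.13948
752,1.13711
753,1.13475
754,1.13239
755,1.13003
756,1.12767
757,1.12532
758,1.12296
759,1.12061
760,1.11827
761,1.11592
762,1.11358
763,1.11124
764,1.1089
765,1.10656
766,1.10423
767,1.10189
768,1.09957
769,1.09724
770,1.09492
771,1.09259
772,1.09027
773,1.08796
774,1.08564
775,1.08333
776,1.08103
777,1.07872
778,1.07642
779,1.07412
780,1.07182
781,1.06953
782,1.06723
783,1.06494
784,1.06266
785,1.06038
786,1.0581
787,1.05582
788,1.05354
789,1.05127
790,1.049
791,1.04674
792,1.04448
793,1.04222
794,1.03996
795,1.03771
796,1.03546
797,1.03321
798,1.03097
799,1.02873
800,1.02649
801,1.02425
802,1.02202
803,1.0198
804,1.01757
805,1.01535
806,1.01313
807,1.01092
808,1.00871
809,1.0065
810,1.00429
811,1.00209
812,0.999895
813,0.9977
814,0.995509
815,0.993321
816,0.991137
817,0.988956
818,0.986778
819,0.984604
820,0.982434
821,0.980267
822,0.978103
823,0.975943
824,0.973787
825,0.971634
826,0.969484
827,0.967338
828,0.965196
829,0.963057
830,0.960922
831,0.95879
832,0.956662
833,0.954538
834,0.952417
835,0.9503
836,0.948187
837,0.946077
838,0.943971
839,0.941868
840,0.939769
841,0.937674
842,0.935583
843,0.933495
844,0.931411
845,0.929331
846,0.927254
847,0.925181
848,0.923112
849,0.921047
850,0.918985
851,0.916927
852,0.914873
853,0.912823
854,0.910776
855,0.908733
856,0.906694
857,0.904659
858,0.902628
859,0.9006
860,0.898576
861,0.896556
862,0.89454
863,0.892528
864,0.890519
865,0.888514
866,0.886513
867,0.884516
868,0.882523
869,0.880534
870,0.878548
871,0.876566
872,0.874588
873,0.872614
874,0.870644
875,0.868678
876,0.866715
877,0.864757
878,0.862802
879,0.860851
880,0.858904
881,0.856961
882,0.855022
883,0.853087
884,0.851155
885,0.849227
886,0.847304
887,0.845384
888,0.843468
889,0.841556
890,0.839648
891,0.837743
892,0.835843
893,0.833946
894,0.832054
895,0.830165
896,0.82828
897,0.826399
898,0.824522
899,0.822649
900,0.820779
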